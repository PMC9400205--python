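"""Synthetic genotype / coverage / annotation generator with ground truth.

Genotypes follow the Balding-Nichols model: each site draws an ancestral
frequency, each population draws its own frequency from a Beta distribution
whose spread is set by a differentiation parameter F (equal to the expected
FST against the ancestral pool), and individuals draw Binomial(2, p)
dosages.  Sweeps push the target population's frequency toward the nearer
fixation point by an intensity alpha, which removes local diversity and
inflates local differentiation — the two signals the outlier scan looks
for.  Sites are unlinked; windows aggregate independent sites, which is
adequate because every implemented statistic is site-decomposable.

Coverage is Poisson per 1-kb window around mean depth x a per-sample
lognormal library factor x a dosage factor: 1 on autosomes for both sexes,
1 / 0.5 (F / M) on the X, and background b / 0.5 on the Y.

Each emitted artifact draws from its own seed-sequence stream derived from
``cfg.seed``, so any single artifact is reproducible in isolation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (GeneInterval, GenotypeMatrix, CoverageTrack, SampleMetadata,
                 write_bed, write_coverage, write_sample_metadata, write_vcf)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    kind: str = "autosome"  # autosome | X | Y

    def __post_init__(self):
        if self.kind not in ("autosome", "X", "Y"):
            raise ValueError(f"chromosome kind {self.kind!r} unknown")


@dataclass(frozen=True)
class PopSpec:
    label: str
    n: int                 # diploid individuals
    fst: float = 0.0       # Balding-Nichols differentiation parameter

    def __post_init__(self):
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("population F must be in [0, 1)")


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    start: int             # 0-based half-open
    end: int
    target: str            # population label
    alpha: float = 0.9     # intensity: 0 no sweep, 1 full fixation

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("sweep intensity alpha must be in [0, 1]")


@dataclass(frozen=True)
class AdmixedSpec:
    sample_id: str
    proportions: dict[str, float]  # population label -> ancestry fraction
    sex: str = "unknown"

    def __post_init__(self):
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("ancestry proportions must sum to 1")


@dataclass
class SimConfig:
    """Study conditions for the generator; defaults mirror a resequencing
    cohort at ~17x depth with 1 variant per ~100 bp."""

    seed: int = 0
    chromosomes: list[ChromSpec] = field(default_factory=list)
    populations: list[PopSpec] = field(default_factory=list)
    site_density: float = 0.01          # expected variants per bp
    p_anc_low: float = 0.05             # ancestral-frequency sampler bounds
    p_anc_high: float = 0.95
    sweeps: list[SweepSpec] = field(default_factory=list)
    admixed: list[AdmixedSpec] = field(default_factory=list)
    mean_depth: float = 17.0
    depth_noise_sd: float = 0.1         # sd of log per-sample library factor
    y_female_background: float = 0.02   # female mismapping fraction on Y
    missing_rate: float = 0.0
    coverage_window: int = 1000

    def __post_init__(self):
        if self.site_density <= 0:
            raise ValueError("site_density must be positive")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        for s in self.sweeps:
            if s.target not in labels:
                raise ValueError(f"sweep target {s.target!r} is not a population")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    positions: np.ndarray              # (m,) 1-based, autosomal sites only
    chrom: np.ndarray                  # (m,)
    pop_freqs: dict[str, np.ndarray]   # post-sweep per-site frequencies
    sweeps: list[SweepSpec]
    chrom_kinds: dict[str, str]
    ancestry: dict[str, dict[str, float]]
    sex: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_sites": int(len(self.positions)),
            "sweeps": [asdict(s) for s in self.sweeps],
            "chrom_kinds": self.chrom_kinds,
            "ancestry": self.ancestry,
            "sex": self.sex,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------

def bn_population_freq(p_anc, f_pop: float, rng: np.random.Generator):
    """Balding-Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral frequency; F = 0 returns the ancestral frequency exactly."""
    p_anc = np.asarray(p_anc, dtype=float)
    if f_pop == 0.0:
        return p_anc.copy()
    scale = (1.0 - f_pop) / f_pop
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def inject_sweep(p_pop, alpha: float):
    """Push frequencies toward the nearer fixation point:
    p' = (1 - alpha) p + alpha [p >= 0.5].  Expected heterozygosity never
    increases; alpha = 1 fixes every site."""
    p = np.asarray(p_pop, dtype=float)
    return (1.0 - alpha) * p + alpha * (p >= 0.5)


def build_samples(cfg: SimConfig) -> list[SampleMetadata]:
    """Deterministic sample sheet: per population, samples labelled
    <pop>_<i> with sexes alternating F, M; admixed individuals appended
    under population label 'ADMIXED'."""
    meta = []
    for pop in cfg.populations:
        for i in range(pop.n):
            meta.append(SampleMetadata(f"{pop.label}_{i + 1:02d}", pop.label,
                                       "F" if i % 2 == 0 else "M"))
    for a in cfg.admixed:
        meta.append(SampleMetadata(a.sample_id, "ADMIXED", a.sex))
    return meta


def expected_site_heterozygosity(cfg: SimConfig, f_pop: float) -> float:
    """Analytic E[2p(1-p)] within a population under the generator:
    uniform ancestral frequencies on [low, high] spread by Balding-Nichols F."""
    lo, hi = cfg.p_anc_low, cfg.p_anc_high
    mu = (lo + hi) / 2.0
    var = (hi - lo) ** 2 / 12.0
    e_p_one_minus_p = mu - (mu ** 2 + var)
    return 2.0 * (1.0 - f_pop) * e_p_one_minus_p


def calibrate_site_density(target_pi: float, cfg: SimConfig, f_pop: float) -> float:
    """Site density per bp at which analytic expected per-bp diversity under
    the generator equals ``target_pi``."""
    het = expected_site_heterozygosity(cfg, f_pop)
    if het <= 0:
        raise ValueError("degenerate ancestral-frequency sampler")
    return target_pi / het


def simulate_genotypes(cfg: SimConfig, vcf_path: str | Path | None = None,
                       meta_path: str | Path | None = None
                       ) -> tuple[GenotypeMatrix, list[SampleMetadata], SimTruth]:
    """Draw the genotype matrix (autosomes only; the sex-linkage scan is
    coverage-based) plus sample sheet and ground truth; optionally write
    them as VCF / TSV.  Deterministic for a fixed config."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    autosomes = [c for c in cfg.chromosomes if c.kind == "autosome"]
    if not autosomes:
        raise ValueError("need at least one autosome for genotypes")
    meta = build_samples(cfg)

    chroms, positions = [], []
    for c in autosomes:
        m_c = rng.poisson(cfg.site_density * c.length)
        pos = np.sort(rng.choice(c.length, size=min(m_c, c.length),
                                 replace=False)) + 1
        positions.append(pos)
        chroms.append(np.full(len(pos), c.name, dtype=object))
    pos = np.concatenate(positions)
    chrom = np.concatenate(chroms)
    m = len(pos)

    p_anc = rng.uniform(cfg.p_anc_low, cfg.p_anc_high, size=m)
    pop_freqs: dict[str, np.ndarray] = {}
    for popspec in cfg.populations:
        p = bn_population_freq(p_anc, popspec.fst, rng)
        pop_freqs[popspec.label] = p
    for s in cfg.sweeps:
        in_region = (chrom == s.chrom) & (pos - 1 >= s.start) & (pos - 1 < s.end)
        p = pop_freqs[s.target]
        p[in_region] = inject_sweep(p[in_region], s.alpha)

    n = len(meta)
    dosage = np.empty((m, n), dtype=np.int8)
    col = 0
    for popspec in cfg.populations:
        p = pop_freqs[popspec.label]
        block = rng.binomial(2, p[:, None], size=(m, popspec.n))
        dosage[:, col:col + popspec.n] = block
        col += popspec.n
    pop_order = [p.label for p in cfg.populations]
    for a in cfg.admixed:
        q = np.array([a.proportions.get(lbl, 0.0) for lbl in pop_order])
        cum = np.cumsum(q)
        copies = np.zeros(m, dtype=np.int8)
        for _ in range(2):
            src = np.searchsorted(cum, rng.random(m), side="right")
            src = np.minimum(src, len(pop_order) - 1)
            freq_at = np.stack([pop_freqs[lbl] for lbl in pop_order])[src, np.arange(m)]
            copies += (rng.random(m) < freq_at).astype(np.int8)
        dosage[:, col] = copies
        col += 1

    if cfg.missing_rate > 0:
        dosage[rng.random((m, n)) < cfg.missing_rate] = -1

    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    ref = _BASES[ref_idx]
    alt = [(str(_BASES[(ref_idx[i] + alt_shift[i]) % 4]),) for i in range(m)]

    gm = GenotypeMatrix(chrom=chrom, pos=pos.astype(np.int64),
                        ref=ref.astype(object), alt=alt, dosage=dosage,
                        samples=[s.sample_id for s in meta])
    gm.validate()
    truth = SimTruth(
        positions=pos, chrom=chrom, pop_freqs=pop_freqs, sweeps=list(cfg.sweeps),
        chrom_kinds={c.name: c.kind for c in cfg.chromosomes},
        ancestry={a.sample_id: dict(a.proportions) for a in cfg.admixed},
        sex={s.sample_id: s.sex for s in meta},
    )
    if vcf_path is not None:
        write_vcf(gm, vcf_path,
                  contig_lengths={c.name: c.length for c in autosomes})
    if meta_path is not None:
        write_sample_metadata(meta, meta_path)
    return gm, meta, truth


_DOSAGE = {
    ("autosome", "F"): 1.0, ("autosome", "M"): 1.0, ("autosome", "unknown"): 1.0,
    ("X", "F"): 1.0, ("X", "M"): 0.5, ("X", "unknown"): 1.0,
    ("Y", "M"): 0.5, ("Y", "unknown"): 0.0,
}


def simulate_coverage(cfg: SimConfig, path: str | Path | None = None
                      ) -> tuple[CoverageTrack, list[SampleMetadata], SimTruth]:
    """Per-1-kb-window Poisson depth with sex-specific chromosome dosage."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    meta = build_samples(cfg)
    n = len(meta)
    sd = cfg.depth_noise_sd
    # lognormal library-size factor with mean 1
    factors = (np.exp(rng.normal(-sd * sd / 2.0, sd, size=n)) if sd > 0
               else np.ones(n))

    chroms, starts, ends, depths = [], [], [], []
    w = cfg.coverage_window
    for c in cfg.chromosomes:
        n_win = (c.length + w - 1) // w
        start = np.arange(n_win, dtype=np.int64) * w
        end = np.minimum(start + w, c.length)
        lam = np.empty((n_win, n))
        for j, s in enumerate(meta):
            if c.kind == "Y" and s.sex == "F":
                g = cfg.y_female_background
            else:
                g = _DOSAGE[(c.kind, s.sex)]
            lam[:, j] = cfg.mean_depth * factors[j] * g
        # partial terminal windows scale with their covered fraction
        lam *= ((end - start) / w)[:, None]
        depths.append(rng.poisson(lam).astype(float))
        chroms.append(np.full(n_win, c.name, dtype=object))
        starts.append(start)
        ends.append(end)

    track = CoverageTrack(
        chrom=np.concatenate(chroms), start=np.concatenate(starts),
        end=np.concatenate(ends), depth=np.vstack(depths),
        samples=[s.sample_id for s in meta], width=w)
    track.validate()
    truth = SimTruth(
        positions=np.empty(0, dtype=np.int64), chrom=np.empty(0, dtype=object),
        pop_freqs={}, sweeps=list(cfg.sweeps),
        chrom_kinds={c.name: c.kind for c in cfg.chromosomes},
        ancestry={a.sample_id: dict(a.proportions) for a in cfg.admixed},
        sex={s.sample_id: s.sex for s in meta},
    )
    if path is not None:
        write_coverage(track, path)
    return track, meta, truth


def simulate_gene_annotation(cfg: SimConfig, n_genes: int, n_categories: int = 10,
                             bed_path: str | Path | None = None,
                             categories_path: str | Path | None = None,
                             min_len: int = 1000, max_len: int = 5000
                             ) -> tuple[list[GeneInterval], dict[str, list[str]]]:
    """Non-overlapping random gene intervals on the autosomes plus a random
    gene -> category assignment (for enrichment testing).  Seeded."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    autosomes = [c for c in cfg.chromosomes if c.kind == "autosome"]
    total = sum(c.length for c in autosomes)
    if n_genes * max_len > total:
        raise ValueError("genes do not fit in the genome")
    genes: list[GeneInterval] = []
    last_end: dict[str, int] = {}
    # draw candidate starts genome-wide, place greedily left to right
    per_chrom = {c.name: c for c in autosomes}
    candidates = []
    for c in autosomes:
        starts = np.sort(rng.integers(0, c.length - max_len,
                                      size=max(4 * n_genes, 16)))
        candidates.extend((c.name, int(s)) for s in starts)
    rng.shuffle(candidates)
    candidates.sort(key=lambda t: (t[0], t[1]))
    gid = 1
    for name, s in candidates:
        if gid > n_genes:
            break
        length = int(rng.integers(min_len, max_len + 1))
        e = min(s + length, per_chrom[name].length)
        if s >= last_end.get(name, 0) and e > s:
            genes.append(GeneInterval(name, s, e, f"gene{gid:04d}"))
            last_end[name] = e
            gid += 1
    if len(genes) < n_genes:
        raise ValueError("could not place all genes without overlap; "
                         "lower n_genes or enlarge the genome")
    cats = {g.gene_id: [f"cat{int(rng.integers(1, n_categories + 1)):02d}"]
            for g in genes}
    if bed_path is not None:
        write_bed(genes, bed_path)
    if categories_path is not None:
        with open(categories_path, "w") as fh:
            fh.write("gene\tcategory\n")
            for g in genes:
                for c in cats[g.gene_id]:
                    fh.write(f"{g.gene_id}\t{c}\n")
    return genes, cats
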