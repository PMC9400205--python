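"""Variant-site quality and population-genetic filters.

The pipeline applies, in order: GATK-style hard filters on INFO annotations,
a biallelic restriction, a genotype-missingness ceiling, a minor-allele-
frequency floor, and an exact Hardy-Weinberg test.  All inequalities are
strict exactly as conventionally printed: a site at QD = 2.0, at 10%
missingness, or at MAF = 0.05 is on the excluded side of its cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, SiteAnnotations


@dataclass(frozen=True)
class FilterThresholds:
    """Cutoffs for every site filter; defaults are the standard hard-filter
    recommendations plus a 10% missingness / 5% MAF / 1e-3 HWE screen."""

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    missing_max: float = 0.10
    maf_min: float = 0.05
    hwe_alpha: float = 0.001
    gq_min: int = 30  # genotype-level mask, applied only before distance/PCA

    def __post_init__(self):
        if not (0.0 <= self.missing_max <= 1.0):
            raise ValueError("missing_max must be in [0, 1]")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")


@dataclass
class FilterReport:
    """Per-site outcome of the filter cascade.

    Each excluded site is counted once, under the first rule it failed; so
    ``n_kept + sum(counts.values()) == n_total``.
    """

    kept: np.ndarray                  # (m,) bool
    first_fail: np.ndarray            # (m,) str, "" for kept sites
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.kept)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def to_frame(self):
        import pandas as pd
        rows = [("kept", self.n_kept)] + sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["rule", "n_sites"])


RULE_ORDER = ("hard_filter", "not_biallelic", "all_missing",
              "missingness", "maf", "hwe")


def hard_filter(ann: SiteAnnotations, t: FilterThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask for the INFO-annotation hard filters.

    A site fails if any *present* annotation violates its cutoff; a missing
    annotation cannot fail a site (the variant-caller convention for sites
    where an annotation is uncomputable, e.g. rank sums without hets).
    """
    t = t or FilterThresholds()
    with np.errstate(invalid="ignore"):
        fail = (
            (ann.QD < t.qd_min)
            | (ann.MQ < t.mq_min)
            | (ann.FS > t.fs_max)
            | (ann.SOR > t.sor_max)
            | (ann.MQRankSum < t.mqranksum_min)
            | (ann.ReadPosRankSum < t.readposranksum_min)
        )
    return ~np.nan_to_num(fail, nan=False).astype(bool)


def biallelic_filter(gm: GenotypeMatrix) -> np.ndarray:
    """Keep sites carrying exactly one alt allele (spanning-deletion ``*``
    alleles count as an extra allele and are dropped)."""
    return np.array(
        [len(a) == 1 and a[0] != "*" for a in gm.alt], dtype=bool
    )


def missingness_maf_filter(gm: GenotypeMatrix, t: FilterThresholds | None = None,
                           sample_idx: np.ndarray | None = None
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keep-masks for missingness and MAF, plus an all-missing mask.

    Returns ``(miss_ok, maf_ok, all_missing)``; the MAF of an all-missing
    site is undefined and such sites are reported separately.
    """
    t = t or FilterThresholds()
    d = gm.dosage if sample_idx is None else gm.dosage[:, sample_idx]
    called = d != MISSING
    n_called = called.sum(axis=1)
    n_total = d.shape[1]
    all_missing = n_called == 0

    miss_rate = (n_total - n_called) / n_total
    miss_ok = miss_rate < t.missing_max

    alt = np.where(called, d, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf_ok = np.where(all_missing, False, maf > t.maf_min)
    return miss_ok, maf_ok, all_missing


@lru_cache(maxsize=100_000)
def _levene_distribution(n: int, n_a: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Exact distribution of the heterozygote count given ``n`` diploids and
    ``n_a`` copies of the A allele (Levene's conditional distribution)."""
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    hets = tuple(range(rare % 2, rare + 1, 2))
    logp = []
    for h in hets:
        x_ra = (min(n_a, n_b) - h) // 2   # rare-allele homozygotes
        x_rb = n - h - x_ra
        lp = (gammaln(n + 1) - gammaln(x_ra + 1) - gammaln(h + 1) - gammaln(x_rb + 1)
              + h * np.log(2.0)
              + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))
        logp.append(lp)
    p = np.exp(np.array(logp))
    p /= p.sum()  # guard rounding; the distribution sums to 1 analytically
    return hets, tuple(p)


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Levene/Haldane conditional test).

    The p-value sums the conditional probabilities of every heterozygote
    count no more probable than the observed one, given the allele counts.
    Symmetric in the allele labels; monomorphic sites return 1.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0 or n_aa_hom + n_het + n_bb_hom < 1:
        raise ValueError("genotype counts must be non-negative and sum to >= 1")
    n = n_aa_hom + n_het + n_bb_hom
    n_a = 2 * n_aa_hom + n_het
    hets, probs = _levene_distribution(n, n_a)
    probs = np.array(probs)
    p_obs = probs[hets.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_pvalues(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None) -> np.ndarray:
    """Exact HWE p-value per site over the pooled (or given) samples."""
    d = gm.dosage if sample_idx is None else gm.dosage[:, sample_idx]
    n_hom_ref = (d == 0).sum(axis=1)
    n_het = (d == 1).sum(axis=1)
    n_hom_alt = (d == 2).sum(axis=1)
    out = np.ones(gm.n_sites)
    for i in range(gm.n_sites):
        tot = n_hom_ref[i] + n_het[i] + n_hom_alt[i]
        if tot >= 1:
            out[i] = hwe_exact_test(int(n_hom_ref[i]), int(n_het[i]), int(n_hom_alt[i]))
    return out


def gq_mask(gm: GenotypeMatrix, gq_min: int = 30) -> GenotypeMatrix:
    """Set genotypes with quality below ``gq_min`` to missing (used before
    the distance-matrix / PCA stage).  A matrix without GQ is returned as is."""
    if gm.gq is None:
        return gm
    masked = gm.dosage.copy()
    masked[(gm.gq != MISSING) & (gm.gq < gq_min)] = MISSING
    return GenotypeMatrix(gm.chrom, gm.pos, gm.ref, list(gm.alt), masked,
                          list(gm.samples), gq=gm.gq)


def apply_all_filters(gm: GenotypeMatrix, ann: SiteAnnotations | None = None,
                      t: FilterThresholds | None = None,
                      hwe_sample_idx: np.ndarray | None = None
                      ) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full site-filter cascade and report first-failure counts.

    Order: hard filters -> biallelic -> all-missing -> missingness -> MAF ->
    HWE (p < alpha dropped).  The HWE test is pooled across all samples by
    default; pass ``hwe_sample_idx`` to test within a subset instead.
    Idempotent: filtering an already-filtered matrix keeps every site.
    """
    t = t or FilterThresholds()
    m = gm.n_sites
    if ann is None:
        ann = SiteAnnotations.empty(m)
    if ann.n_sites != m:
        raise ValueError("annotations not aligned to genotype matrix")

    first_fail = np.full(m, "", dtype=object)
    alive = np.ones(m, dtype=bool)

    def _mark(fail_mask: np.ndarray, rule: str) -> None:
        nonlocal alive
        newly = alive & fail_mask
        first_fail[newly] = rule
        alive = alive & ~fail_mask

    _mark(~hard_filter(ann, t), "hard_filter")
    _mark(~biallelic_filter(gm), "not_biallelic")
    miss_ok, maf_ok, all_missing = missingness_maf_filter(gm, t)
    _mark(all_missing, "all_missing")
    _mark(~miss_ok, "missingness")
    _mark(~maf_ok, "maf")
    # HWE is the costly test; run it only on still-alive sites
    idx_alive = np.flatnonzero(alive)
    if len(idx_alive):
        p = hwe_pvalues(gm.take_sites(idx_alive), hwe_sample_idx)
        hwe_fail = np.zeros(m, dtype=bool)
        hwe_fail[idx_alive] = p < t.hwe_alpha
        _mark(hwe_fail, "hwe")

    counts = {r: int((first_fail == r).sum()) for r in RULE_ORDER
              if (first_fail == r).any()}
    report = FilterReport(kept=alive, first_fail=first_fail, counts=counts)
    return gm.take_sites(alive), report
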