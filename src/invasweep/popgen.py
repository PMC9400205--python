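"""Sliding-window nucleotide diversity and two-population Weir-Cockerham FST.

Both statistics are site-decomposable.  Per-site quantities are computed once
as vectors; window aggregation is a cumulative-sum lookup over the (sorted)
site positions, so overlapping windows (step < size) cost nothing extra.

The FST estimator is Weir & Cockerham (1984) with "weighted" (ratio-of-sums)
window aggregation: FST(window) = sum(a) / sum(a + b + c) over usable sites,
where a, b and c are the among-population, among-individual-within-population
and within-individual variance components.  Negative values are legitimate
estimates near zero differentiation and are never clamped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 5-kb windows advanced in 2.5-kb steps by default."""

    size_bp: int = 5000
    step_bp: int = 2500
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.step_bp <= self.size_bp):
            raise ValueError("need 0 < step_bp <= size_bp")


def make_windows(spec: WindowSpec, chrom: str) -> np.ndarray:
    """(k, 2) array of 0-based half-open windows tiling ``chrom``.

    Starts run 0, step, 2*step, ... while start < length; the final window is
    truncated at the chromosome end.  A chromosome shorter than one window
    yields a single window spanning it entirely.
    """
    if chrom not in spec.chrom_lengths:
        raise KeyError(f"chromosome {chrom!r} not in window spec")
    length = spec.chrom_lengths[chrom]
    starts = np.arange(0, length, spec.step_bp, dtype=np.int64)
    ends = np.minimum(starts + spec.size_bp, length)
    return np.column_stack([starts, ends])


# ---------------------------------------------------------------------------
# per-site quantities

def pop_site_stats(gm: GenotypeMatrix, sample_idx: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_called_diploids, alt_frequency, het_fraction) for a
    population given by sample column indices.  Frequency and het fraction
    are NaN where no genotype is called."""
    d = gm.dosage[:, sample_idx]
    called = d != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, d, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, (d == 1).sum(axis=1) / n, np.nan)
    return n, p, h


def site_pi(alt_count: int, allele_total: int) -> float:
    """Unbiased per-site diversity 2 j (n - j) / (n (n - 1)) for j alt
    alleles among n sampled allele copies.  Undefined below n = 2."""
    j, n = alt_count, allele_total
    if n < 2:
        raise ValueError("site_pi needs at least 2 allele copies")
    if not (0 <= j <= n):
        raise ValueError("alt count outside [0, n]")
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def _site_pi_vector(gm: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    d = gm.dosage[:, sample_idx]
    called = d != MISSING
    n = 2 * called.sum(axis=1)              # allele copies
    j = np.where(called, d, 0).sum(axis=1)  # alt copies
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi[n < 2] = 0.0  # sites with < 1 called diploid pair carry no information
    return pi


def fst_components(n1: float, p1: float, h1: float,
                   n2: float, p2: float, h2: float) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) for one biallelic site
    and two populations with ``n_i`` called diploids, alt frequency ``p_i``
    and observed heterozygote fraction ``h_i``.

    Raises if the site is unusable (a population empty, or mean sample size
    too small for the finite-sample corrections).
    """
    r = 2
    if min(n1, n2) < 1:
        raise ValueError("both populations need at least one called genotype")
    nbar = (n1 + n2) / r
    if nbar <= 1:
        raise ValueError("mean sample size must exceed 1 diploid")
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        raise ValueError("n_c <= 0; site unusable")
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _fst_component_vectors(gm: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (a, a+b+c, usable) across all sites."""
    n1, p1, h1 = pop_site_stats(gm, idx_a)
    n2, p2, h2 = pop_site_stats(gm, idx_b)
    r = 2
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    usable = (n1 >= 1) & (n2 >= 1) & (nbar > 1) & (nc > 0)
    a = np.where(usable, a, 0.0)
    d = a + np.where(usable, b + c, 0.0)
    return a, d, usable


# ---------------------------------------------------------------------------
# window aggregation

def _window_sums(values: np.ndarray, pos0: np.ndarray, windows: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sum ``values`` (aligned to sorted 0-based positions) over each
    [start, end) window; also return per-window site counts."""
    cs = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(pos0, windows[:, 0], side="left")
    hi = np.searchsorted(pos0, windows[:, 1], side="left")
    return cs[hi] - cs[lo], (hi - lo).astype(np.int64)


def windowed_pi(gm: GenotypeMatrix, sample_idx: np.ndarray, spec: WindowSpec
                ) -> pd.DataFrame:
    """Per-window per-bp nucleotide diversity for one population.

    pi(window) = sum of per-site pi over variants in the window, divided by
    the window span; positions without a variant contribute zero.  Windows
    containing no variant are reported with pi = NaN so that downstream
    medians and quantiles can exclude them.
    """
    if len(sample_idx) == 0:
        raise ValueError("population has no samples")
    pi_sites = _site_pi_vector(gm, sample_idx)
    frames = []
    for chrom in spec.chrom_lengths:
        windows = make_windows(spec, chrom)
        on = gm.chrom == chrom
        pos0 = gm.pos[on] - 1
        sums, counts = _window_sums(pi_sites[on], pos0, windows)
        span = (windows[:, 1] - windows[:, 0]).astype(float)
        pi = np.where(counts > 0, sums / span, np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": windows[:, 0], "end": windows[:, 1],
            "n_variants": counts, "pi": pi,
        }))
    return pd.concat(frames, ignore_index=True)


def windowed_fst(gm: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray,
                 spec: WindowSpec) -> pd.DataFrame:
    """Per-window weighted (ratio-of-sums) Weir-Cockerham FST between two
    populations.  Windows with no usable site or a non-positive component
    denominator get FST = NaN (excluded from medians/quantiles)."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both populations need at least one sample")
    a, d, usable = _fst_component_vectors(gm, idx_a, idx_b)
    frames = []
    for chrom in spec.chrom_lengths:
        windows = make_windows(spec, chrom)
        on = gm.chrom == chrom
        pos0 = gm.pos[on] - 1
        sum_a, _ = _window_sums(a[on], pos0, windows)
        sum_d, _ = _window_sums(d[on], pos0, windows)
        n_used, _ = _window_sums(usable[on].astype(float), pos0, windows)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where((sum_d > 0) & (n_used > 0), sum_a / sum_d, np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": windows[:, 0], "end": windows[:, 1],
            "n_sites_used": n_used.astype(np.int64), "fst": fst,
        }))
    return pd.concat(frames, ignore_index=True)


def median_stat(values) -> float:
    """Median over non-excluded (non-NaN) window values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no non-excluded values to take a median of")
    return float(np.median(v))


def compare_distributions(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of two sets
    of window statistics.  Exact for small untied samples, tie-corrected
    normal approximation otherwise.  Returns (U, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def build_window_stats_table(gm: GenotypeMatrix, pop_indices: dict[str, np.ndarray],
                             contrasts: list[tuple[str, str]], spec: WindowSpec
                             ) -> pd.DataFrame:
    """Assemble the per-window statistics table: one pi column per population
    and one weighted-FST column per contrast, on a shared window grid."""
    base = None
    for pop, idx in pop_indices.items():
        t = windowed_pi(gm, idx, spec).rename(columns={"pi": f"pi_{pop}"})
        if base is None:
            base = t
        else:
            base = base.merge(t.drop(columns="n_variants"),
                              on=["chrom", "start", "end"])
    for ref_pop, target_pop in contrasts:
        t = windowed_fst(gm, pop_indices[ref_pop], pop_indices[target_pop], spec)
        base = base.merge(
            t[["chrom", "start", "end", "fst"]].rename(
                columns={"fst": f"fst_{ref_pop}_{target_pop}"}),
            on=["chrom", "start", "end"])
    return base


def write_window_stats(df: pd.DataFrame, path, header_lines: list[str] | None = None
                       ) -> None:
    """Write the window table with 1-based inclusive BIN coordinates (the
    dialect of the usual windowed-statistics tools)."""
    out = df.copy()
    out.insert(1, "BIN_START", out.pop("start") + 1)
    out.insert(2, "BIN_END", out.pop("end"))
    out = out.rename(columns={"chrom": "CHROM"})
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")
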