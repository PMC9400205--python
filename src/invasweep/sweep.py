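"""Selective-sweep caller: pi-ratio, upper-quantile outliers on FST and
pi-ratio, their intersection, region merging, gene overlap and enrichment.

A sweep in the target population locally removes diversity and inflates
differentiation, so candidate regions are windows that sit in the upper
tail of BOTH the FST distribution and the pi-ratio distribution, where the
ratio is oriented reference/target (diversity loss in the target pushes the
ratio up).  The threshold is an order statistic with a strict inequality,
which is reproducible and safe under ties.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneInterval


@dataclass(frozen=True)
class SweepParams:
    """Outlier-scan settings: upper quantile, pi pseudocount, and which
    population the scan treats as the sweep target."""

    q: float = 0.95
    epsilon: float = 1e-5
    target: str = ""          # population whose diversity loss is scanned for
    reference: str = ""

    def __post_init__(self):
        if not (0.0 < self.q < 1.0):
            raise ValueError("quantile q must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("pseudocount epsilon must be positive")


@dataclass
class SweepRegion:
    """A maximal run of flagged windows, with peak statistics and the genes
    it overlaps."""

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_fst: float
    peak_pi_ratio: float
    gene_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int   # selected genes in category
    K: int   # background genes in category
    n: int   # selected genes total
    N: int   # background genes total
    p_value: float
    p_adjusted: float


def pi_ratio(pi_ref: np.ndarray, pi_target: np.ndarray, epsilon: float = 1e-5
             ) -> np.ndarray:
    """Per-window (pi_ref + eps) / (pi_target + eps); NaN where either
    population's window was empty (NaN in, NaN out)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pi_ref = np.asarray(pi_ref, dtype=float)
    pi_target = np.asarray(pi_target, dtype=float)
    return (pi_ref + epsilon) / (pi_target + epsilon)


def quantile_outliers(values, q: float = 0.95) -> np.ndarray:
    """Flag values strictly above the ceil(q*W)-th order statistic of the W
    non-NaN values.  NaN entries are never flagged.  For distinct values and
    W divisible by 1/(1-q), exactly a (1-q) fraction is flagged."""
    v = np.asarray(values, dtype=float)
    finite = ~np.isnan(v)
    w = int(finite.sum())
    need = math.ceil(1.0 / (1.0 - q))
    if w < need:
        raise ValueError(
            f"only {w} usable windows; the upper-{1 - q:.0%} rule needs at "
            f"least {need} — use more/longer chromosomes or smaller windows")
    order = np.sort(v[finite])
    threshold = order[math.ceil(q * w) - 1]
    mask = np.zeros_like(v, dtype=bool)
    mask[finite] = v[finite] > threshold
    return mask


def intersect_outliers(fst_mask: np.ndarray, ratio_mask: np.ndarray) -> np.ndarray:
    fst_mask = np.asarray(fst_mask, dtype=bool)
    ratio_mask = np.asarray(ratio_mask, dtype=bool)
    if fst_mask.shape != ratio_mask.shape:
        raise ValueError("outlier masks are not aligned")
    return fst_mask & ratio_mask


def merge_regions(windows: pd.DataFrame, flagged: np.ndarray) -> list[SweepRegion]:
    """Merge overlapping or book-ended flagged windows (columns chrom, start,
    end, fst, pi_ratio) into maximal regions; peak stats are maxima over the
    member windows."""
    flagged = np.asarray(flagged, dtype=bool)
    sub = windows.loc[flagged].sort_values(["chrom", "start"])
    regions: list[SweepRegion] = []
    cur = None
    for row in sub.itertuples(index=False):
        if cur is not None and row.chrom == cur.chrom and row.start <= cur.end:
            cur.end = max(cur.end, int(row.end))
            cur.n_windows += 1
            cur.peak_fst = max(cur.peak_fst, float(row.fst))
            cur.peak_pi_ratio = max(cur.peak_pi_ratio, float(row.pi_ratio))
        else:
            cur = SweepRegion(str(row.chrom), int(row.start), int(row.end), 1,
                              float(row.fst), float(row.pi_ratio))
            regions.append(cur)
    return regions


def overlap_genes(regions: list[SweepRegion], genes: list[GeneInterval]
                  ) -> list[str]:
    """Attach overlapping genes (>= 1 bp, half-open arithmetic) to each
    region in place; return the unique overlapped gene list in genomic
    order, each gene counted once even if it spans several regions."""
    unique: list[str] = []
    seen: set[str] = set()
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    for region in sorted(regions, key=lambda r: (r.chrom, r.start)):
        region.gene_ids = []
        for g in by_chrom.get(region.chrom, []):
            if g.start < region.end and region.start < g.end:
                region.gene_ids.append(g.gene_id)
                if g.gene_id not in seen:
                    seen.add(g.gene_id)
                    unique.append(g.gene_id)
    return unique


def enrichment_test(selected, background, categories: dict[str, list[str]]
                    ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``selected`` genes against
    ``background``, per category, with Benjamini-Hochberg correction across
    categories.  ``categories`` maps gene id -> list of category ids; genes
    outside the background are ignored."""
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    selected = set(selected) & background
    cat_bg: dict[str, set[str]] = {}
    for gene, cats in categories.items():
        if gene in background:
            for c in cats:
                cat_bg.setdefault(c, set()).add(gene)
    n_total = len(background)
    n_sel = len(selected)
    results = []
    for cat, genes_in_cat in sorted(cat_bg.items()):
        big_k = len(genes_in_cat)
        k = len(selected & genes_in_cat)
        p = float(hypergeom.sf(k - 1, n_total, big_k, n_sel)) if k > 0 else 1.0
        results.append((cat, k, big_k, p))
    if not results:
        return []
    pvals = [r[3] for r in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(cat, k, big_k, n_sel, n_total, p, float(pa))
        for (cat, k, big_k, p), pa in zip(results, p_adj)
    ]


def sweep_scan(window_stats: pd.DataFrame, fst_col: str, pi_ref_col: str,
               pi_target_col: str, params: SweepParams,
               genes: list[GeneInterval] | None = None
               ) -> tuple[pd.DataFrame, list[SweepRegion], list[str]]:
    """Run the full scan on a window-statistics table.

    Returns the table augmented with pi_ratio/outlier columns, the merged
    candidate regions, and the unique overlapped gene list.  Windows lacking
    either statistic are excluded from both tails and from the intersection.
    """
    df = window_stats.copy()
    df["pi_ratio"] = pi_ratio(df[pi_ref_col].to_numpy(),
                              df[pi_target_col].to_numpy(), params.epsilon)
    fst = df[fst_col].to_numpy(dtype=float)
    ratio = df["pi_ratio"].to_numpy(dtype=float)
    excluded = np.isnan(fst) | np.isnan(ratio)
    fst_m = np.where(excluded, np.nan, fst)
    ratio_m = np.where(excluded, np.nan, ratio)
    df["fst_outlier"] = quantile_outliers(fst_m, params.q)
    df["ratio_outlier"] = quantile_outliers(ratio_m, params.q)
    df["sweep_candidate"] = intersect_outliers(df["fst_outlier"].to_numpy(),
                                               df["ratio_outlier"].to_numpy())
    view = df.rename(columns={fst_col: "fst"})[
        ["chrom", "start", "end", "fst", "pi_ratio"]]
    regions = merge_regions(view, df["sweep_candidate"].to_numpy())
    gene_list = overlap_genes(regions, genes) if genes is not None else []
    return df, regions, gene_list


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "n_windows": [r.n_windows for r in regions],
        "peak_fst": [r.peak_fst for r in regions],
        "peak_pi_ratio": [r.peak_pi_ratio for r in regions],
        "genes": [",".join(r.gene_ids) for r in regions],
    })
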