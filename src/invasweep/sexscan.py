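"""Female:male coverage-ratio classifier for autosome / X / Y assignment.

With an XY system, females carry two X copies and no Y, males one of each,
so relative to autosomes the expected female:male depth ratio is 1 on
autosomes, 2 on the X, and near zero on the Y (females receive only a small
mismapping background there).  On a log2 scale the chromosome-level medians
sit near 0, +1 and below -1 respectively, which is the classification rule
implemented here.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageTrack, SampleMetadata


@dataclass(frozen=True)
class SexScanParams:
    """Bands and guards for the log2(F:M) classifier.

    ``delta`` is the pseudocount keeping log2 finite at zero depth; left as
    None it resolves to 0.1x the overall mean of the two group-mean tracks.
    ``autosome_band``/``x_band`` are half-widths around the expected modes
    0 and +1; the Y rule is the hard cutoff m <= -1.
    """

    delta: float | None = None
    min_male_depth: float = 1.0
    autosome_band: float = 0.35
    x_band: float = 0.35
    y_max: float = -1.0
    min_windows: int = 10

    def resolve_delta(self, f_mean: np.ndarray, m_mean: np.ndarray) -> float:
        if self.delta is not None:
            if self.delta <= 0:
                raise ValueError("delta must be positive")
            return self.delta
        overall = float(np.mean(np.concatenate([f_mean, m_mean])))
        return max(0.1 * overall, 1e-6)


@dataclass(frozen=True)
class SexCall:
    chrom: str
    median_log2_ratio: float  # NaN when undetermined for lack of windows
    n_windows: int
    call: str  # autosome | X-linked | Y-linked | undetermined


def group_mean_coverage(track: CoverageTrack, meta: list[SampleMetadata]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window arithmetic mean depth of the female and male groups.
    Unknown-sex samples are ignored; an empty sex group is an error."""
    by_id = {m.sample_id: m.sex for m in meta}
    f_cols = [j for j, s in enumerate(track.samples) if by_id.get(s) == "F"]
    m_cols = [j for j, s in enumerate(track.samples) if by_id.get(s) == "M"]
    if not f_cols or not m_cols:
        raise ValueError("need at least one female and one male sample with "
                         "known sex among the coverage columns")
    return track.depth[:, f_cols].mean(axis=1), track.depth[:, m_cols].mean(axis=1)


def fm_log_ratio(f_mean: np.ndarray, m_mean: np.ndarray, delta: float,
                 min_male_depth: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-window log2((F + delta) / (M + delta)) and a usability mask;
    windows where male mean depth falls below the floor are unusable (their
    ratio is dominated by the pseudocount)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    f_mean = np.asarray(f_mean, dtype=float)
    m_mean = np.asarray(m_mean, dtype=float)
    ratio = np.log2((f_mean + delta) / (m_mean + delta))
    usable = m_mean >= min_male_depth
    return ratio, usable


def classify_chromosomes(track: CoverageTrack, log2_ratio: np.ndarray,
                         usable: np.ndarray, params: SexScanParams
                         ) -> list[SexCall]:
    """Median log2(F:M) per chromosome over usable windows, mapped to a call.

    Bands: |m| <= autosome_band -> autosome; |m - 1| <= x_band -> X-linked;
    m <= y_max -> Y-linked; otherwise (or with too few usable windows)
    undetermined.  The median makes the call robust to isolated mismapping
    windows.
    """
    calls = []
    for chrom in pd.unique(track.chrom):
        on = (track.chrom == chrom) & usable
        n = int(on.sum())
        if n < params.min_windows:
            calls.append(SexCall(str(chrom), float("nan"), n, "undetermined"))
            continue
        m = float(np.median(log2_ratio[on]))
        if abs(m) <= params.autosome_band:
            call = "autosome"
        elif abs(m - 1.0) <= params.x_band:
            call = "X-linked"
        elif m <= params.y_max:
            call = "Y-linked"
        else:
            call = "undetermined"
        calls.append(SexCall(str(chrom), m, n, call))
    return calls


def sex_scan(track: CoverageTrack, meta: list[SampleMetadata],
             params: SexScanParams | None = None
             ) -> tuple[list[SexCall], pd.DataFrame]:
    """Full scan: group means -> pseudocounted log2 ratios -> chromosome
    calls.  Also returns the per-window table (chromosome boxplot / scatter
    substrate)."""
    params = params or SexScanParams()
    f_mean, m_mean = group_mean_coverage(track, meta)
    delta = params.resolve_delta(f_mean, m_mean)
    ratio, usable = fm_log_ratio(f_mean, m_mean, delta, params.min_male_depth)
    calls = classify_chromosomes(track, ratio, usable, params)
    table = pd.DataFrame({
        "chrom": track.chrom, "start": track.start, "end": track.end,
        "f_mean": f_mean, "m_mean": m_mean,
        "log2_fm": ratio, "usable": usable,
    })
    return calls, table


def calls_to_frame(calls: list[SexCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [c.chrom for c in calls],
        "median_log2_fm": [c.median_log2_ratio for c in calls],
        "n_usable_windows": [c.n_windows for c in calls],
        "call": [c.call for c in calls],
    })
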