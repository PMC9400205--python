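"""Parameter-recovery experiments: simulate under known conditions, run the
estimators, and report what they recover.

These are the validation runs the package stands on: Balding-Nichols FST
recovery at published differentiation levels, diversity calibration,
coverage-ratio recovery for the sex-chromosome dosage model, and sweep
recall.  Each function is deterministic given its seed and returns plain
numbers.
"""
from __future__ import annotations

import numpy as np

from .popgen import WindowSpec, median_stat, windowed_fst, windowed_pi
from .sexscan import SexScanParams, fm_log_ratio, group_mean_coverage, sex_scan
from .simulate import (ChromSpec, PopSpec, SimConfig, SweepSpec,
                       calibrate_site_density, simulate_coverage,
                       simulate_genotypes)
from .sweep import SweepParams, sweep_scan
from .popgen import build_window_stats_table


def fst_recovery(f_param: float, seed: int, n_diploids: int = 10,
                 genome_bp: int = 5_000_000, site_density: float = 0.04
                 ) -> tuple[float, int]:
    """Median 5-kb/2.5-kb windowed weighted Weir-Cockerham FST between two
    Balding-Nichols populations simulated at differentiation ``f_param``.

    Returns (median FST, number of sites simulated).  At the default scale
    (~200k unlinked sites, 10 diploids per population) the median recovers
    the parameter to within about +/-0.01.
    """
    cfg = SimConfig(
        seed=seed,
        chromosomes=[ChromSpec("chr1", genome_bp)],
        populations=[PopSpec("REF", n_diploids, f_param),
                     PopSpec("TGT", n_diploids, f_param)],
        site_density=site_density,
    )
    gm, meta, _ = simulate_genotypes(cfg)
    idx = {p: gm.sample_indices([m.sample_id for m in meta
                                 if m.population == p])
           for p in ("REF", "TGT")}
    spec = WindowSpec(5000, 2500, {"chr1": genome_bp})
    fst = windowed_fst(gm, idx["REF"], idx["TGT"], spec)
    return median_stat(fst["fst"]), gm.n_sites


def pi_recovery(target_pi: float, seed: int, genome_bp: int = 2_000_000,
                n_diploids: int = 10) -> tuple[float, int]:
    """Median windowed per-bp diversity from a generator whose site density
    is calibrated analytically so expected diversity equals ``target_pi``."""
    base = SimConfig(seed=seed, chromosomes=[ChromSpec("chr1", genome_bp)],
                     populations=[PopSpec("POP", n_diploids, 0.0)])
    density = calibrate_site_density(target_pi, base, 0.0)
    cfg = SimConfig(seed=seed, chromosomes=base.chromosomes,
                    populations=base.populations, site_density=density)
    gm, _, _ = simulate_genotypes(cfg)
    spec = WindowSpec(5000, 2500, {"chr1": genome_bp})
    pi = windowed_pi(gm, np.arange(n_diploids), spec)
    usable = pi["pi"].dropna()
    return median_stat(pi["pi"]), int(len(usable))


def _coverage_track(kind: str, seed: int, genome_bp: int, mean_depth: float,
                    depth_noise_sd: float):
    cfg = SimConfig(
        seed=seed,
        chromosomes=[ChromSpec("sim", genome_bp, kind)],
        populations=[PopSpec("P", 10, 0.0)],  # alternating F/M -> 5 + 5
        mean_depth=mean_depth,
        depth_noise_sd=depth_noise_sd,
    )
    track, meta, _ = simulate_coverage(cfg)
    return track, meta


def coverage_ratio_recovery(kind: str, seed: int, genome_bp: int = 10_000_000,
                            mean_depth: float = 17.0,
                            depth_noise_sd: float = 0.0) -> tuple[float, int]:
    """Median per-1-kb-window female:male mean-coverage ratio on one
    simulated chromosome of the given kind (Poisson depth by default).
    Expected: ~1 on an autosome, ~2 on the X."""
    track, meta = _coverage_track(kind, seed, genome_bp, mean_depth,
                                  depth_noise_sd)
    f_mean, m_mean = group_mean_coverage(track, meta)
    ok = m_mean > 0
    return float(np.median(f_mean[ok] / m_mean[ok])), int(ok.sum())


def y_log2_ratio_recovery(seed: int, genome_bp: int = 5_000_000,
                          mean_depth: float = 17.0, delta: float = 0.1
                          ) -> tuple[float, int]:
    """Chromosome-level median log2((F + delta)/(M + delta)) on a simulated
    Y chromosome (female coverage is mismapping background only); the
    classification rule expects a value at or below -1."""
    track, meta = _coverage_track("Y", seed, genome_bp, mean_depth, 0.0)
    f_mean, m_mean = group_mean_coverage(track, meta)
    ratio, usable = fm_log_ratio(f_mean, m_mean, delta)
    return float(np.median(ratio[usable])), int(usable.sum())


def sex_classification_recovery(seed: int, genome_bp: int = 10_000_000,
                                y_bp: int = 5_000_000,
                                depth_noise_sd: float = 0.1
                                ) -> dict[str, str]:
    """Run the full classifier on one simulated autosome + X + Y; returns
    chromosome -> call."""
    cfg = SimConfig(
        seed=seed,
        chromosomes=[ChromSpec("auto", genome_bp),
                     ChromSpec("chrX", genome_bp, "X"),
                     ChromSpec("chrY", y_bp, "Y")],
        populations=[PopSpec("P", 10, 0.0)],
        depth_noise_sd=depth_noise_sd,
    )
    track, meta, _ = simulate_coverage(cfg)
    calls, _ = sex_scan(track, meta, SexScanParams())
    return {c.chrom: c.call for c in calls}


def sweep_recall(seed: int, alpha: float = 0.9, genome_bp: int = 5_000_000,
                 sweep_span: tuple[int, int] = (2_000_000, 2_200_000),
                 f_param: float = 0.042, site_density: float = 0.02
                 ) -> tuple[float, float]:
    """Recall on truth-sweep windows and false-positive rate elsewhere for
    the FST x pi-ratio upper-5%-quantile intersection, with one sweep of
    intensity ``alpha`` injected in the target population.

    Truth windows are those lying entirely inside the swept interval.
    """
    start, end = sweep_span
    cfg = SimConfig(
        seed=seed,
        chromosomes=[ChromSpec("chr1", genome_bp)],
        populations=[PopSpec("REF", 10, f_param), PopSpec("TGT", 10, f_param)],
        site_density=site_density,
        sweeps=[SweepSpec("chr1", start, end, "TGT", alpha)],
    )
    gm, meta, _ = simulate_genotypes(cfg)
    idx = {p: gm.sample_indices([m.sample_id for m in meta
                                 if m.population == p])
           for p in ("REF", "TGT")}
    spec = WindowSpec(5000, 2500, {"chr1": genome_bp})
    stats = build_window_stats_table(gm, idx, [("REF", "TGT")], spec)
    df, _, _ = sweep_scan(stats, "fst_REF_TGT", "pi_REF", "pi_TGT",
                          SweepParams(target="TGT", reference="REF"))
    truth = (df["start"] >= start) & (df["end"] <= end)
    recall = float(df.loc[truth, "sweep_candidate"].mean())
    fpr = float(df.loc[~truth, "sweep_candidate"].mean())
    return recall, fpr
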