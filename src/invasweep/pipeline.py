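"""Config-driven orchestration: filter -> window stats -> sweep scan ->
sex scan -> structure, with a deterministic summary report.

Every stage is a thin call into the library modules; outputs are TSV/Newick
files whose header comments record the tool version, a config hash and the
seed, so a rerun on identical inputs is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .filters import FilterThresholds, apply_all_filters, gq_mask
from .io import (read_coverage, read_intervals, read_sample_metadata, read_vcf,
                 write_vcf)
from .popgen import (WindowSpec, build_window_stats_table, median_stat,
                     write_window_stats)
from .sexscan import SexScanParams, calls_to_frame, sex_scan
from .structure import ibs_distance, nj_tree, pca, to_newick
from .sweep import SweepParams, regions_to_frame, sweep_scan

log = logging.getLogger("invasweep")


@dataclass
class PipelineConfig:
    vcf: str
    metadata: str
    outdir: str
    coverage: str | None = None
    genes: str | None = None
    contrasts: list[tuple[str, str]] = field(default_factory=list)  # (ref, target)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    window: WindowSpec = field(default_factory=WindowSpec)
    sweep: SweepParams = field(default_factory=SweepParams)
    sexscan: SexScanParams = field(default_factory=SexScanParams)
    pca_components: int = 2
    apply_gq_mask_for_structure: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = FilterThresholds(**kwargs["thresholds"])
        if "window" in kwargs:
            kwargs["window"] = WindowSpec(**kwargs["window"])
        if "sweep" in kwargs:
            kwargs["sweep"] = SweepParams(**kwargs["sweep"])
        if "sexscan" in kwargs:
            kwargs["sexscan"] = SexScanParams(**kwargs["sexscan"])
        if "contrasts" in kwargs:
            kwargs["contrasts"] = [tuple(c) for c in kwargs["contrasts"]]
        return cls(**kwargs)

    def config_hash(self) -> str:
        # identifies the analysis settings; where outputs land is not part
        # of what was computed
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(cfg: PipelineConfig) -> list[str]:
    return [f"invasweep {__version__} config={cfg.config_hash()} seed={cfg.seed}"]


def _write_tsv(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``cfg.outdir``.

    Returns a result bundle (in-memory objects plus the summary dict).
    Aborts with the stage name on any stage error.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(cfg)
    summary: dict = {"version": __version__, "config": cfg.config_hash(),
                     "seed": cfg.seed}

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("read inputs")
    try:
        meta = read_sample_metadata(cfg.metadata)
        gm, ann = read_vcf(cfg.vcf)
        populations = sorted({m.population for m in meta
                              if m.population != "ADMIXED"})
        for ref, target in cfg.contrasts:
            for p in (ref, target):
                if p not in {m.population for m in meta}:
                    raise ValueError(f"contrast population {p!r} absent from "
                                     f"metadata {cfg.metadata}")

        current = stage("filter")
        gm_f, report = apply_all_filters(gm, ann, cfg.thresholds)
        summary["n_sites_input"] = int(report.n_total)
        summary["n_sites_kept"] = int(report.n_kept)
        write_vcf(gm_f, out / "filtered.vcf")
        _write_tsv(report.to_frame(), out / "filter_report.tsv", header)

        current = stage("window statistics")
        if not cfg.window.chrom_lengths:
            lengths = {str(c): int(gm_f.pos[gm_f.chrom == c].max())
                       for c in pd.unique(gm_f.chrom)}
            spec = WindowSpec(cfg.window.size_bp, cfg.window.step_bp, lengths)
        else:
            spec = cfg.window
        pop_idx = {p: gm_f.sample_indices(
            [m.sample_id for m in meta if m.population == p])
            for p in populations}
        stats = build_window_stats_table(gm_f, pop_idx, cfg.contrasts, spec)
        write_window_stats(stats.copy(), out / "window_stats.tsv", header)
        summary["median_pi"] = {p: median_stat(stats[f"pi_{p}"])
                                for p in populations}
        summary["median_fst"] = {
            f"{r}_vs_{t}": median_stat(stats[f"fst_{r}_{t}"])
            for r, t in cfg.contrasts}

        current = stage("sweep scan")
        genes = read_intervals(cfg.genes) if cfg.genes else None
        sweep_out = {}
        for ref, target in cfg.contrasts:
            params = SweepParams(cfg.sweep.q, cfg.sweep.epsilon,
                                 target=target, reference=ref)
            df, regions, gene_list = sweep_scan(
                stats, f"fst_{ref}_{target}", f"pi_{ref}", f"pi_{target}",
                params, genes)
            tag = f"{ref}_vs_{target}"
            _write_tsv(regions_to_frame(regions),
                       out / f"sweep_regions_{tag}.tsv", header)
            sweep_out[tag] = {"regions": regions, "genes": gene_list,
                              "n_flagged": int(df["sweep_candidate"].sum())}
            summary.setdefault("sweep", {})[tag] = {
                "n_flagged_windows": int(df["sweep_candidate"].sum()),
                "n_regions": len(regions),
                "n_unique_genes": len(gene_list)}

        current = stage("sex scan")
        sex_calls = None
        if cfg.coverage:
            track = read_coverage(cfg.coverage)
            sex_calls, win_table = sex_scan(track, meta, cfg.sexscan)
            _write_tsv(calls_to_frame(sex_calls), out / "sex_calls.tsv", header)
            _write_tsv(win_table, out / "sex_windows.tsv", header)
            summary["sex_calls"] = {c.chrom: c.call for c in sex_calls}

        current = stage("structure")
        gm_s = gq_mask(gm_f, cfg.thresholds.gq_min) \
            if cfg.apply_gq_mask_for_structure else gm_f
        dm = ibs_distance(gm_s)
        pd.DataFrame(dm.matrix, index=dm.ids, columns=dm.ids).to_csv(
            out / "distance.tsv", sep="\t")
        tree = nj_tree(dm)
        (out / "tree.nwk").write_text(to_newick(tree) + "\n")
        pc = pca(gm_s, k=cfg.pca_components)
        pca_df = pd.DataFrame(
            pc.coordinates,
            columns=[f"PC{i + 1}" for i in range(cfg.pca_components)])
        pca_df.insert(0, "sample", pc.sample_ids)
        _write_tsv(pca_df, out / "pca.tsv", header)
        summary["pca_variance_explained"] = [round(float(v), 6)
                                             for v in pc.variance_explained]
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {current!r}: {e}") from e

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"summary": summary, "window_stats": stats, "sweeps": sweep_out,
            "sex_calls": sex_calls, "tree": tree, "pca": pc,
            "filter_report": report}
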