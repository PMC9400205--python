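"""Windowed diversity and differentiation.

Computes per-population nucleotide diversity and per-contrast weighted
Weir-Cockerham FST in 5-kb windows stepped by 2.5 kb, then summarises the
medians and compares FST distributions between contrasts with the Wilcoxon
rank-sum test.  Writes results/window_stats.tsv.
"""
from pathlib import Path

import pandas as pd

from invasweep import (WindowSpec, build_window_stats_table,
                       compare_distributions, median_stat,
                       read_sample_metadata, read_vcf)
from invasweep.popgen import write_window_stats

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "results"
CONTRASTS = [("CAMT", "CHN"), ("AZCO", "CHN"), ("WIMN", "CHN")]


def main():
    gm, _ = read_vcf(OUT / "filtered.vcf")
    meta = read_sample_metadata(OUT / "sim" / "meta.tsv")
    lengths = {str(c): int(gm.pos[gm.chrom == c].max())
               for c in pd.unique(gm.chrom)}
    spec = WindowSpec(5000, 2500, lengths)
    pops = sorted({m.population for m in meta if m.population != "ADMIXED"})
    idx = {p: gm.sample_indices([m.sample_id for m in meta
                                 if m.population == p]) for p in pops}
    stats = build_window_stats_table(gm, idx, CONTRASTS, spec)
    write_window_stats(stats, OUT / "window_stats.tsv")

    print("median windowed pi per population:")
    for p in pops:
        print(f"  {p}: {median_stat(stats[f'pi_{p}']):.3e}")
    print("median windowed weighted FST per contrast:")
    for r, t in CONTRASTS:
        print(f"  {r} vs {t}: {median_stat(stats[f'fst_{r}_{t}']):.3f}")
    a = stats["fst_CAMT_CHN"]
    b = stats["fst_WIMN_CHN"]
    u, p = compare_distributions(a, b)
    print(f"CAMT-CHN vs WIMN-CHN FST distributions: U={u:.0f}, p={p:.2e}")


if __name__ == "__main__":
    main()
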