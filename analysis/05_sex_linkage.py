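"""Sex-chromosome identification from read coverage.

Computes per-1-kb-window female and male group mean depth, the pseudocounted
log2(F:M) ratio, and a chromosome-level call from the median.  Writes
results/sex_calls.tsv and results/sex_windows.tsv.
"""
from pathlib import Path

from invasweep import (SexScanParams, read_coverage, read_sample_metadata,
                       sex_scan)
from invasweep.sexscan import calls_to_frame

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "results"


def main():
    track = read_coverage(OUT / "sim" / "coverage.tsv")
    meta = read_sample_metadata(OUT / "sim" / "meta.tsv")
    calls, table = sex_scan(track, meta, SexScanParams())
    calls_to_frame(calls).to_csv(OUT / "sex_calls.tsv", sep="\t", index=False)
    table.to_csv(OUT / "sex_windows.tsv", sep="\t", index=False)
    for c in calls:
        print(f"{c.chrom}: median log2(F:M) = {c.median_log2_ratio:+.3f} "
              f"over {c.n_windows} windows -> {c.call}")


if __name__ == "__main__":
    main()
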