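"""Build the synthetic study cohort.

Four populations on a 5-Mb two-autosome genome plus an X and a Y for the
coverage scan: one low-diversity focal population (CHN) and three source
populations whose Balding-Nichols parameters are calibrated so the expected
pairwise differentiation against CHN is 0.042 (CAMT), 0.084 (AZCO) and
0.112 (WIMN) — pairwise FST under this model is close to the mean of the
two per-population parameters.  One 200-kb selective sweep (intensity 0.9)
is injected in CHN, and three individuals are admixed CAMT/CHN.

Writes sim.vcf, meta.tsv, coverage.tsv, genes.bed, categories.tsv and
truth.json under results/sim/.
"""
from pathlib import Path

from invasweep import (AdmixedSpec, ChromSpec, PopSpec, SimConfig, SweepSpec,
                       simulate_coverage, simulate_gene_annotation,
                       simulate_genotypes)
from invasweep.io import write_sample_metadata
from invasweep.simulate import build_samples

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "results" / "sim"

F_CHN = 0.042
CONFIG = SimConfig(
    seed=20260929,
    chromosomes=[
        ChromSpec("chr1", 3_000_000),
        ChromSpec("chr2", 2_000_000),
        ChromSpec("chrX", 1_000_000, "X"),
        ChromSpec("chrY", 500_000, "Y"),
    ],
    populations=[
        PopSpec("CHN", 12, F_CHN),
        PopSpec("CAMT", 12, 2 * 0.042 - F_CHN),
        PopSpec("AZCO", 12, 2 * 0.084 - F_CHN),
        PopSpec("WIMN", 12, 2 * 0.112 - F_CHN),
    ],
    site_density=0.015,
    sweeps=[SweepSpec("chr1", 1_200_000, 1_400_000, "CHN", 0.9)],
    admixed=[AdmixedSpec(f"MIX_{i}", {"CAMT": 0.5, "CHN": 0.5},
                         "F" if i % 2 == 0 else "M") for i in range(3)],
    missing_rate=0.02,
)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    gm, meta, truth = simulate_genotypes(CONFIG, OUT / "sim.vcf")
    write_sample_metadata(build_samples(CONFIG), OUT / "meta.tsv")
    track, _, _ = simulate_coverage(CONFIG, OUT / "coverage.tsv")
    genes, _ = simulate_gene_annotation(CONFIG, 200,
                                        bed_path=OUT / "genes.bed",
                                        categories_path=OUT / "categories.tsv")
    truth.to_json(OUT / "truth.json")
    print(f"simulated {gm.n_sites} sites x {gm.n_samples} samples, "
          f"{track.n_windows} coverage windows, {len(genes)} genes -> {OUT}")
    print(f"truth sweep: chr1:1,200,000-1,400,000 in CHN (alpha=0.9)")


if __name__ == "__main__":
    main()
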