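"""Per-site genetic diversity for ramets and genets, pairwise
Weir-Cockerham F_ST, and PCA structure summaries.

Writes results/tables/genetic_diversity.tsv, fst.tsv and pca_scores.tsv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import numpy as np
import pandas as pd

from clonalpop import clonality, popgen
from clonalpop.vcfio import read_genotype_table, read_sample_table

DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    gm = read_genotype_table(DATA / "genotypes_filtered.tsv")
    samples = read_sample_table(DATA / "samples.tsv")
    site_of = dict(zip(samples["sample_id"], samples["site_code"]))
    sites = np.asarray([site_of[s] for s in gm.sample_ids])
    clones = pd.read_csv(TABLES / "clones.tsv", sep="\t")
    assignment = clonality.ClonalAssignment(
        sample_ids=list(clones["sample_id"]),
        mlg_ids=clones["mlg"].to_numpy(),
        mll_ids=clones["mll"].to_numpy(),
        threshold=np.nan, linkage="average",
    )

    div = pd.concat(
        [
            popgen.diversity_stats(gm, sites, unit=u, assignment=assignment)
            for u in ("ramets", "genets")
        ]
    )
    TABLES.mkdir(parents=True, exist_ok=True)
    div.to_csv(TABLES / "genetic_diversity.tsv", sep="\t", index=False)
    ram = div[div["unit"] == "ramets"]
    print("ramet diversity (negative F_IS = clonal heterozygote excess):")
    print(ram.round(3).to_string(index=False))

    fst = popgen.pairwise_fst(gm, sites)
    fst.to_csv(TABLES / "fst.tsv", sep="\t")
    vals = fst.to_numpy()[~np.eye(len(fst), dtype=bool)]
    print(
        f"pairwise theta: min {np.nanmin(vals):.3f}, "
        f"max {np.nanmax(vals):.3f} (clusters drive the high pairs)"
    )

    pc = popgen.pca(gm, n_axes=3)
    pd.DataFrame(
        pc.scores, index=pc.sample_ids,
        columns=[f"PC{i+1}" for i in range(pc.n_axes)],
    ).to_csv(TABLES / "pca_scores.tsv", sep="\t", index_label="sample_id")
    print(
        "PCA explained variance:",
        np.round(pc.explained_variance_ratio, 3).tolist(),
    )


if __name__ == "__main__":
    main()
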