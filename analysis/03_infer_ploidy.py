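"""Call diploid vs triploid per sample from allele balance at heterozygous
SNPs (binomial likelihood: one peak at 1/2 vs peaks at 1/3 and 2/3).

Reads results/data/variants.vcf; writes results/tables/ploidy.tsv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd

from clonalpop.ploidy import classify_all
from clonalpop.vcfio import read_vcf

DATA = ROOT / "results" / "data"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    data = read_vcf(DATA / "variants.vcf")
    calls = classify_all(data.genotypes, data.depths)
    df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id, "call": c.call,
                "logL_dip": c.loglik_diploid, "logL_trip": c.loglik_triploid,
                "n_sites": c.n_sites, "median_depth": c.median_depth,
            }
            for c in calls
        ]
    )
    TABLES.mkdir(parents=True, exist_ok=True)
    df.to_csv(TABLES / "ploidy.tsv", sep="\t", index=False)
    print(df["call"].value_counts().to_string())
    truth = pd.read_csv(DATA / "truth_samples.tsv", sep="\t")
    merged = df.merge(truth, on="sample_id")
    determined = merged[merged["call"] != "undetermined"]
    acc = (
        determined["call"].map({"diploid": 2, "triploid": 3})
        == determined["ploidy"]
    ).mean()
    print(f"accuracy vs truth on determined samples: {acc:.1%}")


if __name__ == "__main__":
    main()
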