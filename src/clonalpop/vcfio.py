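"""Reading and writing VCF and the tabular side-inputs.

Variants come in as VCF v4.2 with GT and, optionally, AD/DP/GQ per call
(absent fields yield missing sentinels). Reading is delegated to cyvcf2;
writing emits plain-text v4.2 with ``GT:AD:DP:GQ``. Multi-allelic records
are retained but flagged in the locus table so the biallelic filter can
drop them explicitly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, DepthMatrix, GenotypeMatrix


@dataclass
class VcfDataset:
    """Everything parsed from one multi-sample VCF.

    ``site_qual`` is the phred-scaled site QUAL column (NaN where '.'),
    ``genotype_qual`` the per-call GQ matrix (-1 where absent).
    """

    genotypes: GenotypeMatrix
    depths: DepthMatrix
    site_qual: np.ndarray
    genotype_qual: np.ndarray


def read_vcf(path: str | os.PathLike) -> VcfDataset:
    """Parse a VCF into aligned genotype/depth/quality matrices.

    Dosage is the count of the first ALT allele per call; loci are ordered
    by (contig, pos) as encountered. Raises ``ValueError`` on duplicated
    sample ids; malformed records raise from the underlying parser.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # malformed header (incl. duplicated samples)
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicated sample id in {path}")

    contigs, positions, refs, alts, multi, quals = [], [], [], [], [], []
    dos_rows, rd_rows, ad_rows, gq_rows = [], [], [], []
    for v in vcf:
        contigs.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        multi.append(len(v.ALT) > 1)
        quals.append(np.nan if v.QUAL is None else float(v.QUAL))

        dos = np.empty(len(samples), dtype=np.int16)
        for i, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a is not None]
            if not alleles or any(a < 0 for a in alleles):
                dos[i] = MISSING
            else:
                dos[i] = sum(1 for a in alleles if a == 1)
        dos_rows.append(dos)

        ad = v.format("AD")
        if ad is None:
            rd_rows.append(np.zeros(len(samples), dtype=np.int32))
            ad_rows.append(np.zeros(len(samples), dtype=np.int32))
        else:
            ad = np.asarray(ad)
            rd_rows.append(np.maximum(ad[:, 0], 0).astype(np.int32))
            alt_d = ad[:, 1] if ad.shape[1] > 1 else np.zeros(len(samples))
            ad_rows.append(np.maximum(alt_d, 0).astype(np.int32))

        gq = v.format("GQ")
        if gq is None:
            gq_arr = v.gt_quals
            gq_rows.append(
                np.full(len(samples), -1, dtype=np.float64)
                if gq_arr is None
                else np.asarray(gq_arr, dtype=np.float64)
            )
        else:
            gq_rows.append(np.asarray(gq, dtype=np.float64).reshape(-1))
    vcf.close()

    loci = pd.DataFrame(
        {
            "contig": contigs,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "multiallelic": np.asarray(multi, dtype=bool),
        }
    )
    n_loci = len(loci)
    shape = (len(samples), n_loci)
    dosages = (
        np.stack(dos_rows, axis=1) if n_loci else np.zeros(shape, dtype=np.int16)
    )
    ref_d = np.stack(rd_rows, axis=1) if n_loci else np.zeros(shape, dtype=np.int32)
    alt_d = np.stack(ad_rows, axis=1) if n_loci else np.zeros(shape, dtype=np.int32)
    gqm = np.stack(gq_rows, axis=1) if n_loci else np.zeros(shape)

    order = np.lexsort((loci["pos"].to_numpy(), loci["contig"].to_numpy()))
    if not np.array_equal(order, np.arange(n_loci)):
        loci = loci.iloc[order].reset_index(drop=True)
        dosages, ref_d, alt_d, gqm = (
            dosages[:, order],
            ref_d[:, order],
            alt_d[:, order],
            gqm[:, order],
        )

    gm = GenotypeMatrix(sample_ids=samples, loci=loci, dosages=dosages)
    return VcfDataset(
        genotypes=gm,
        depths=DepthMatrix(ref_d, alt_d),
        site_qual=np.asarray(quals)[order] if n_loci else np.asarray(quals),
        genotype_qual=gqm,
    )


def _gt_string(dosage: int, ploidy: int) -> str:
    """Diploid-style GT for a dosage call; intermediate dosages code as het."""
    if dosage == MISSING:
        return "./."
    if dosage == 0:
        return "0/0"
    if dosage == ploidy:
        return "1/1"
    return "0/1"


def write_vcf(
    gm: GenotypeMatrix,
    path: str | os.PathLike,
    depths: DepthMatrix | None = None,
    site_qual: np.ndarray | None = None,
    genotype_qual: np.ndarray | None = None,
) -> None:
    """Write a v4.2 VCF with GT:AD:DP:GQ fields.

    Dosage calls are written diploid-style regardless of sample ploidy
    (intermediate dosages become ``0/1``), matching diploid variant calling
    of mixed-ploidy samples; read depths carry the only triploidy signal.
    """
    if depths is not None:
        depths.check_aligned(gm)
    lines = ["##fileformat=VCFv4.2", "##source=clonalpop"]
    for contig in pd.unique(gm.loci["contig"]):
        lines.append(f"##contig=<ID={contig}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids),
    ]
    ref = gm.loci["ref"] if "ref" in gm.loci else pd.Series(["A"] * gm.n_loci)
    alt = gm.loci["alt"] if "alt" in gm.loci else pd.Series(["T"] * gm.n_loci)
    for j in range(gm.n_loci):
        qual = "."
        if site_qual is not None and np.isfinite(site_qual[j]):
            qual = f"{site_qual[j]:g}"
        fields = [
            str(gm.loci["contig"].iloc[j]),
            str(int(gm.loci["pos"].iloc[j])),
            ".",
            str(ref.iloc[j]),
            str(alt.iloc[j]),
            qual,
            ".",
            ".",
            "GT:AD:DP:GQ",
        ]
        for i in range(gm.n_samples):
            gt = _gt_string(int(gm.dosages[i, j]), int(gm.ploidy[i]))
            if depths is None:
                ad, dp = ".,.", "."
            else:
                rd, al = int(depths.ref_depth[i, j]), int(depths.alt_depth[i, j])
                ad, dp = f"{rd},{al}", str(rd + al)
            gq = (
                str(int(genotype_qual[i, j]))
                if genotype_qual is not None and genotype_qual[i, j] >= 0
                else "."
            )
            fields.append(f"{gt}:{ad}:{dp}:{gq}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_genotype_table(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Lossless TSV dump: one row per sample, one column per contig:pos locus."""
    cols = [
        f"{c}:{p}" for c, p in zip(gm.loci["contig"], gm.loci["pos"])
    ]
    df = pd.DataFrame(gm.dosages, index=gm.sample_ids, columns=cols)
    df.insert(0, "ploidy", gm.ploidy)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_genotype_table(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    ploidy = df.pop("ploidy").to_numpy()
    contigs, positions = zip(*(c.rsplit(":", 1) for c in df.columns)) if len(
        df.columns
    ) else ((), ())
    loci = pd.DataFrame(
        {"contig": list(contigs), "pos": np.asarray(positions, dtype=np.int64)}
    )
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        loci=loci,
        dosages=df.to_numpy(),
        ploidy=ploidy,
    )


def read_sample_table(path: str | os.PathLike) -> pd.DataFrame:
    """Sample->site table: sample_id, site_code, lat, lon (TSV)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "site_code"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample table needs columns {sorted(required)}")
    return df


def read_env_table(path: str | os.PathLike) -> pd.DataFrame:
    """Site x variable environment table: site, variable, baseline_value, future_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"site", "variable", "baseline_value", "future_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"env table needs columns {sorted(required)}")
    return df
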