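"""Core in-memory containers for genotype and read-depth data.

The substrate of every downstream statistic is a samples x loci matrix of
alt-allele dosages over biallelic SNPs, together with per-genotype ref/alt
read depths. Dosages are small integers in ``{0..ploidy}`` with ``-1`` as
the missing sentinel; ploidy is recorded per sample (default 2) because
triploid individuals can occur alongside diploids in the same dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Missing-genotype sentinel used throughout.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage calls for a set of samples over ordered biallelic loci.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (rows).
    loci
        DataFrame with at least ``contig`` and ``pos`` columns (1-based,
        VCF-style coordinates), one row per locus (columns of ``dosages``).
        Optional columns: ``ref``, ``alt``, ``multiallelic`` (bool flag).
    dosages
        ``(n_samples, n_loci)`` integer array; entry is the number of copies
        of the alt allele, or :data:`MISSING`.
    ploidy
        Per-sample ploidy, shape ``(n_samples,)``; defaults to 2 everywhere.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    dosages: np.ndarray
    ploidy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.ploidy is None:
            self.ploidy = np.full(len(self.sample_ids), 2, dtype=np.int16)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int16)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if self.ploidy.shape != (len(self.sample_ids),):
            raise ValueError("ploidy must be per-sample")
        valid = self.dosages != MISSING
        if np.any(self.dosages[valid] < 0):
            raise ValueError("negative dosage that is not the missing sentinel")
        if np.any(self.dosages[valid] > self.ploidy[:, None].repeat(self.n_loci, 1)[valid]):
            raise ValueError("dosage exceeds sample ploidy")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_samples, n_loci)`` mask, True where the call is missing."""
        return self.dosages == MISSING

    # -- subsetting -----------------------------------------------------
    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            loci=self.loci.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            dosages=self.dosages[idx, :],
            ploidy=self.ploidy[idx],
        )

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    # -- per-locus summaries --------------------------------------------
    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alt allele count, total called allele count), missing excluded."""
        called = ~self.missing_mask
        dos = np.where(called, self.dosages, 0)
        alt = dos.sum(axis=0)
        total = (called * self.ploidy[:, None]).sum(axis=0)
        return alt.astype(np.int64), total.astype(np.int64)

    def minor_allele_counts(self) -> np.ndarray:
        alt, total = self.allele_counts()
        return np.minimum(alt, total - alt)

    def alt_freqs(self) -> np.ndarray:
        """Per-locus alt-allele frequency among called genotypes (NaN if none)."""
        alt, total = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, alt / np.maximum(total, 1), np.nan)

    def locus_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0) if self.n_samples else np.zeros(self.n_loci)

    def sample_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1) if self.n_loci else np.zeros(self.n_samples)

    def is_polymorphic(self) -> np.ndarray:
        mac = self.minor_allele_counts()
        return mac > 0

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.loci[["contig", "pos"]].equals(other.loci[["contig", "pos"]])
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.ploidy, other.ploidy)
        )


@dataclass
class DepthMatrix:
    """Per-genotype ref/alt read depths aligned to a :class:`GenotypeMatrix`."""

    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int32)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int32)
        if self.ref_depth.shape != self.alt_depth.shape:
            raise ValueError("ref/alt depth shapes differ")
        if np.any(self.ref_depth < 0) or np.any(self.alt_depth < 0):
            raise ValueError("negative read depth")

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def check_aligned(self, gm: GenotypeMatrix) -> None:
        if self.ref_depth.shape != gm.dosages.shape:
            raise ValueError(
                f"depth shape {self.ref_depth.shape} does not match genotype "
                f"shape {gm.dosages.shape}"
            )

    def take_loci(self, idx: np.ndarray) -> "DepthMatrix":
        idx = np.asarray(idx)
        return DepthMatrix(self.ref_depth[:, idx], self.alt_depth[:, idx])

    def take_samples(self, idx: np.ndarray) -> "DepthMatrix":
        idx = np.asarray(idx)
        return DepthMatrix(self.ref_depth[idx, :], self.alt_depth[idx, :])
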