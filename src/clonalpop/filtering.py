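"""Post-caller SNP and sample filtering.

The chain mirrors a conventional hard-filtering recipe for
reduced-representation/WGS SNP data, in three stages run in a fixed order:

1. site-level quality screen (missingness, minor allele count, site QUAL);
2. removal of samples with excessive missingness, then genotype-level
   invalidation (GQ, depth, allele depth, allele balance) followed by the
   no-missing-data and minor-allele-frequency rules;
3. distance thinning per contig, mean-depth bounds, and removal of
   monomorphic or multi-allelic loci.

Every stage reports the loci (and samples) it removed so a run is auditable
stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, DepthMatrix, GenotypeMatrix
from .vcfio import VcfDataset


@dataclass
class FilterConfig:
    """Thresholds of the three-stage filter chain.

    ``allele_depth_mode`` selects the semantics of the minimum allele-depth
    rule: ``"per_allele_het"`` requires both allele depths >= the threshold
    at each heterozygous call (consistent with how allele balance is read
    for ploidy inference); ``"site_sum"`` instead requires each allele's
    depth summed over all samples to reach the threshold.
    """

    max_missing_fraction: float = 0.70
    min_minor_allele_count: int = 3
    min_site_qual: float = 30.0
    min_genotype_quality: float = 20.0
    min_genotype_depth: int = 3
    min_allele_depth: int = 10
    min_maf: float = 0.05
    min_allele_balance: float = 0.10
    sample_max_missing: float = 0.95
    thin_bp: int = 1000
    site_mean_depth_range: tuple[float, float] = (15.0, 100.0)
    allele_depth_mode: str = "per_allele_het"

    def __post_init__(self) -> None:
        lo, hi = self.site_mean_depth_range
        if lo > hi:
            raise ValueError("site_mean_depth_range must be ordered")
        numeric = [
            self.max_missing_fraction,
            self.min_minor_allele_count,
            self.min_site_qual,
            self.min_genotype_quality,
            self.min_genotype_depth,
            self.min_allele_depth,
            self.min_maf,
            self.min_allele_balance,
            self.sample_max_missing,
            self.thin_bp,
            lo,
            hi,
        ]
        if any(x < 0 for x in numeric):
            raise ValueError("filter thresholds must be non-negative")
        if self.allele_depth_mode not in ("per_allele_het", "site_sum"):
            raise ValueError(f"unknown allele_depth_mode {self.allele_depth_mode!r}")


@dataclass
class FilterLog:
    """Per-stage locus/sample counts for auditability."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})


def filter_stage1(
    gm: GenotypeMatrix,
    site_qual: np.ndarray,
    config: FilterConfig,
    log: FilterLog | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Site-level screen: missingness, minor allele count and site quality.

    Keeps loci whose missing fraction <= ``max_missing_fraction``, minor
    allele count >= ``min_minor_allele_count`` and QUAL >=
    ``min_site_qual`` (a NaN QUAL, i.e. '.', is not held against a locus).
    Returns the filtered matrix and the kept locus indices.
    """
    if gm.n_loci == 0:
        return gm, np.arange(0)
    site_qual = np.asarray(site_qual, dtype=float)
    miss_ok = gm.locus_missing_fraction() <= config.max_missing_fraction
    mac_ok = gm.minor_allele_counts() >= config.min_minor_allele_count
    qual_ok = ~(site_qual < config.min_site_qual)  # NaN passes
    keep = np.flatnonzero(miss_ok & mac_ok & qual_ok)
    if log is not None:
        log.record(
            "stage1", loci_in=gm.n_loci, loci_out=len(keep),
            fail_missing=int((~miss_ok).sum()), fail_mac=int((~mac_ok).sum()),
            fail_qual=int((~qual_ok).sum()),
        )
    return gm.take_loci(keep), keep


def drop_samples_by_missingness(
    gm: GenotypeMatrix,
    sample_max_missing: float = 0.95,
    log: FilterLog | None = None,
) -> tuple[GenotypeMatrix, list[str], np.ndarray]:
    """Remove samples whose missing fraction exceeds the threshold.

    Returns (filtered matrix, dropped sample ids, kept sample indices).
    Raises if every sample would be dropped, which indicates the threshold
    needs review rather than a meaningful dataset.
    """
    frac = gm.sample_missing_fraction()
    keep = np.flatnonzero(frac <= sample_max_missing)
    dropped = [gm.sample_ids[i] for i in np.flatnonzero(frac > sample_max_missing)]
    if len(keep) == 0:
        raise ValueError(
            "all samples exceed the missingness threshold "
            f"({sample_max_missing}); review the threshold or the input"
        )
    if log is not None:
        log.record(
            "sample_drop", samples_in=gm.n_samples, samples_out=len(keep),
            dropped_ids=dropped,
        )
    return gm.take_samples(keep), dropped, keep


def filter_stage2(
    gm: GenotypeMatrix,
    depths: DepthMatrix,
    config: FilterConfig,
    genotype_qual: np.ndarray | None = None,
    log: FilterLog | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotype-level invalidation, then no-missing-data and MAF rules.

    Calls are first set missing where GQ < ``min_genotype_quality`` (when a
    GQ matrix is supplied), total depth < ``min_genotype_depth``, or — at
    heterozygous calls — the minor allele's read fraction <
    ``min_allele_balance`` or either allele's depth < ``min_allele_depth``
    (per ``allele_depth_mode``). Loci with any missing call after
    invalidation are removed, then loci with MAF < ``min_maf``.
    """
    depths.check_aligned(gm)
    dos = gm.dosages.copy()
    called = dos != MISSING

    invalid = np.zeros_like(called)
    if genotype_qual is not None:
        gq = np.asarray(genotype_qual)
        if gq.shape != dos.shape:
            raise ValueError("genotype_qual shape mismatch")
        invalid |= (gq >= 0) & (gq < config.min_genotype_quality)
    total = depths.total_depth
    invalid |= total < config.min_genotype_depth

    het = called & (dos > 0) & (dos < gm.ploidy[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.minimum(depths.ref_depth, depths.alt_depth) / np.maximum(
            total, 1
        )
    invalid |= het & (minor_frac < config.min_allele_balance)
    if config.allele_depth_mode == "per_allele_het":
        invalid |= het & (
            (depths.ref_depth < config.min_allele_depth)
            | (depths.alt_depth < config.min_allele_depth)
        )

    dos[called & invalid] = MISSING
    gm2 = GenotypeMatrix(gm.sample_ids, gm.loci, dos, gm.ploidy)

    no_missing = ~(gm2.missing_mask.any(axis=0))
    alt, tot = gm2.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(alt, tot - alt) / np.maximum(tot, 1)
    maf_ok = maf >= config.min_maf
    keep_mask = no_missing & maf_ok
    if config.allele_depth_mode == "site_sum":
        keep_mask &= (depths.ref_depth.sum(axis=0) >= config.min_allele_depth) & (
            depths.alt_depth.sum(axis=0) >= config.min_allele_depth
        )
    keep = np.flatnonzero(keep_mask)
    if log is not None:
        log.record(
            "stage2", loci_in=gm.n_loci, loci_out=len(keep),
            calls_invalidated=int((called & invalid).sum()),
            fail_missing=int((~no_missing).sum()), fail_maf=int((~maf_ok).sum()),
        )
    return gm2.take_loci(keep), keep


def thin_positions(contigs: np.ndarray, positions: np.ndarray, thin_bp: int) -> np.ndarray:
    """Greedy first-kept scan: keep a locus iff >= thin_bp from the last
    kept locus on its contig (ascending position; ties kept in input order)."""
    keep = []
    last_kept: dict[str, int] = {}
    order = np.lexsort((np.arange(len(positions)), positions, contigs))
    kept_set = np.zeros(len(positions), dtype=bool)
    for idx in order:
        c, p = contigs[idx], positions[idx]
        if c not in last_kept or p - last_kept[c] >= thin_bp:
            last_kept[c] = p
            kept_set[idx] = True
    keep = np.flatnonzero(kept_set)
    return keep


def filter_stage3(
    gm: GenotypeMatrix,
    depths: DepthMatrix,
    config: FilterConfig,
    log: FilterLog | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Distance thinning, mean-depth bounds, polymorphic biallelic loci only.

    Mean depth is the per-locus mean of total read depth over all samples;
    loci outside ``site_mean_depth_range`` are removed.
    """
    depths.check_aligned(gm)
    if gm.n_loci == 0:
        return gm, np.arange(0)
    thin_keep = np.zeros(gm.n_loci, dtype=bool)
    thin_keep[
        thin_positions(
            gm.loci["contig"].to_numpy(), gm.loci["pos"].to_numpy(), config.thin_bp
        )
    ] = True
    mean_depth = depths.total_depth.mean(axis=0)
    lo, hi = config.site_mean_depth_range
    depth_ok = (mean_depth >= lo) & (mean_depth <= hi)
    poly = gm.is_polymorphic()
    # polymorphic also requires not fixed for alt
    alt, tot = gm.allele_counts()
    poly &= alt < tot
    biallelic = (
        ~gm.loci["multiallelic"].to_numpy()
        if "multiallelic" in gm.loci
        else np.ones(gm.n_loci, dtype=bool)
    )
    keep = np.flatnonzero(thin_keep & depth_ok & poly & biallelic)
    if log is not None:
        log.record(
            "stage3", loci_in=gm.n_loci, loci_out=len(keep),
            fail_thin=int((~thin_keep).sum()), fail_depth=int((~depth_ok).sum()),
            fail_monomorphic=int((~poly).sum()),
            fail_multiallelic=int((~biallelic).sum()),
        )
    return gm.take_loci(keep), keep


def run_filter_chain(
    data: VcfDataset, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, DepthMatrix, FilterLog]:
    """Full chain in canonical order: stage1 -> sample drop -> stage2 -> stage3.

    Returns the analysis-ready genotype matrix (no missing calls, every
    locus polymorphic and biallelic), the aligned depth matrix, and the
    per-stage log.
    """
    config = config or FilterConfig()
    log = FilterLog()
    gm, keep1 = filter_stage1(data.genotypes, data.site_qual, config, log)
    depths = data.depths.take_loci(keep1)
    gq = data.genotype_qual[:, keep1]

    gm, _, keep_s = drop_samples_by_missingness(gm, config.sample_max_missing, log)
    depths = depths.take_samples(keep_s)
    gq = gq[keep_s, :]

    gm, keep2 = filter_stage2(gm, depths, config, gq, log)
    depths = depths.take_loci(keep2)

    gm, keep3 = filter_stage3(gm, depths, config, log)
    depths = depths.take_loci(keep3)
    assert not gm.missing_mask.any()
    return gm, depths, log
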