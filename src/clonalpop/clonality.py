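"""Clonal lineage detection and clonal-diversity statistics.

Partially clonal organisms yield samples (ramets) that may belong to the
same clonal lineage (genet). Because somatic mutations, and residual
genotyping error, introduce small differences between true clonemates,
lineages are defined by clustering the pairwise Hamming distance matrix at
a clone threshold: samples closer than the threshold belong to one
multilocus lineage (MLL, proxy for genets), while exactly identical
genotypes share a multilocus genotype (MLG, proxy for ramets).

The threshold itself is predicted from the distance structure: sweeping the
threshold upward, cluster counts drop at a series of candidate distances;
within-clone distances form the low mode and the first large gap in the
candidate series separates them from between-lineage distances.

Diversity of the resulting clonal structure is summarised by Simpson's
lambda (probability two random samples belong to different lineages) and
the Pareto beta (negative log-log slope of the reverse cumulative
clone-size distribution; low beta = a few dominant clones, infinite when
every lineage is a singleton).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in [0, 1] with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class ClonalAssignment:
    """Per-sample MLG (exact genotype) and MLL (thresholded lineage) ids."""

    sample_ids: list[str]
    mlg_ids: np.ndarray
    mll_ids: np.ndarray
    threshold: float
    linkage: str

    @property
    def n_mlg(self) -> int:
        return len(np.unique(self.mlg_ids))

    @property
    def n_mll(self) -> int:
        return len(np.unique(self.mll_ids))


def hamming_distances(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-count Hamming distance: summed absolute dosage difference,
    normalised by ploidy x L so values lie in [0, 1] and thresholds are
    comparable across datasets. Requires complete data (run the filter
    chain first). Mixed-ploidy input normalises by the maximum ploidy."""
    if gm.missing_mask.any():
        raise ValueError(
            "missing genotypes present; apply the filter chain before "
            "computing clonal distances"
        )
    ploidy = int(gm.ploidy.max()) if gm.n_samples else 2
    raw = pdist(gm.dosages.astype(float), metric="cityblock")
    values = squareform(raw / (ploidy * max(gm.n_loci, 1)))
    return DistanceMatrix(sample_ids=list(gm.sample_ids), values=values)


def _mlg_from_distances(dm: DistanceMatrix) -> np.ndarray:
    """MLG ids: connected components of the distance-0 graph (exact
    genotype equality is transitive, so components are cliques)."""
    n = dm.n
    ids = np.full(n, -1, dtype=int)
    next_id = 0
    for i in range(n):
        if ids[i] == -1:
            members = np.flatnonzero((dm.values[i] == 0.0) & (ids == -1))
            ids[members] = next_id
            ids[i] = next_id
            next_id += 1
    return ids


def _average_linkage_merges(dm: DistanceMatrix):
    """Deterministic agglomeration: repeatedly merge the pair of clusters
    with the smallest average linkage, breaking ties by the lowest member
    sample index. Cluster-to-cluster averages are maintained with the
    Lance-Williams update for average linkage. Returns a list of
    (height, merged member list) per merge."""
    n = dm.n
    if n < 2:
        return []
    D = dm.values.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    sizes = np.ones(n)
    merges = []
    for _ in range(n - 1):
        W = np.where(np.outer(active, active), D, np.inf)
        np.fill_diagonal(W, np.inf)
        h = W.min()
        # tie-break among equal-height pairs: lowest member index first
        ii, jj = np.nonzero(W == h)
        pairs = [(min(members[i][0], members[j][0]),
                  max(members[i][0], members[j][0]), i, j)
                 for i, j in zip(ii, jj) if i < j]
        _, _, a, b = min(pairs)
        # Lance-Williams average-linkage update into slot a
        for k in range(n):
            if active[k] and k not in (a, b):
                D[a, k] = D[k, a] = (
                    sizes[a] * D[a, k] + sizes[b] * D[b, k]
                ) / (sizes[a] + sizes[b])
        active[b] = False
        sizes[a] += sizes[b]
        members[a] = sorted(members[a] + members[b])
        merges.append((float(h), list(members[a])))
    return merges


def assign_mll(
    dm: DistanceMatrix, threshold: float, linkage: str = "average"
) -> ClonalAssignment:
    """Cluster samples into MLLs at the given clone threshold.

    Agglomerative clustering merges the closest pair of clusters while the
    average linkage between them is <= threshold (so threshold 0 merges
    exactly identical genotypes and MLLs coincide with MLGs). Merge order
    is smallest-linkage-first with lowest-sample-index tie-break, making
    the partition deterministic.
    """
    if threshold < 0:
        raise ValueError("clone threshold must be non-negative")
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    n = dm.n
    mll = np.arange(n)
    for height, members in _average_linkage_merges(dm):
        if height > threshold:
            break
        mll[members] = members[0]  # members sorted; lowest index labels
    # relabel compactly in order of first appearance
    _, mll = np.unique(mll, return_inverse=True)
    return ClonalAssignment(
        sample_ids=list(dm.sample_ids),
        mlg_ids=_mlg_from_distances(dm),
        mll_ids=mll,
        threshold=threshold,
        linkage=linkage,
    )


def candidate_thresholds(dm: DistanceMatrix, linkage: str = "average") -> np.ndarray:
    """Distances at which the MLL count changes while sweeping the threshold
    up from 0: the distinct positive merge heights of the agglomeration.
    Identical samples merge already at threshold 0, so an all-identical
    dataset has no candidates. Strictly increasing."""
    if dm.n < 2:
        return np.asarray([])
    heights = [h for h, _ in _average_linkage_merges(dm) if h > 0]
    return np.unique(np.asarray(heights))


def predict_clone_threshold(
    candidates: np.ndarray, fraction: float = 0.5
) -> float:
    """Predict the clone threshold from candidate thresholds.

    Restricts to the first ceil(fraction * m) candidates (at least two, so
    a gap exists), finds the largest gap between consecutive candidates in
    that prefix, and returns the midpoint of the bracketing pair. The
    rationale: within-clone candidate distances are small and tightly
    spaced; the first large gap marks the transition to between-lineage
    distances. Returns 0 with a warning when fewer than two candidates.
    """
    candidates = np.sort(np.asarray(candidates, dtype=float))
    m = len(candidates)
    if m < 2:
        warnings.warn(
            "fewer than two candidate thresholds; returning 0 (no clones "
            "detectable)", stacklevel=2,
        )
        return 0.0
    k = max(2, int(np.ceil(fraction * m)))
    prefix = candidates[:k]
    gaps = np.diff(prefix)
    g = int(np.argmax(gaps))
    return float((prefix[g] + prefix[g + 1]) / 2.0)


def simpson_lambda(sizes) -> float:
    """Simpson's lambda, 1 - sum((n_i/N)^2): the probability that two
    individuals drawn at random belong to different clonal lineages."""
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        return float("nan")
    if np.any(sizes <= 0) or np.any(sizes != np.round(sizes)):
        raise ValueError("clone sizes must be positive integers")
    p = sizes / sizes.sum()
    return float(1.0 - np.sum(p**2))


def pareto_beta(sizes) -> float:
    """Negative slope of the log-log reverse cumulative clone-size
    distribution, fitted by OLS over the distinct observed sizes.

    Few large clones among many small ones give low beta; balanced sizes
    give high beta. When every genet is a singleton no clones are present
    and beta is +infinity; a single distinct size > 1 leaves nothing to
    regress on and returns NaN with a warning.
    """
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0:
        return float("nan")
    if np.any(sizes <= 0):
        raise ValueError("clone sizes must be positive")
    if np.all(sizes == 1):
        return float("inf")
    distinct = np.unique(sizes)
    if len(distinct) < 2:
        warnings.warn(
            "only one distinct clone size; Pareto beta undefined", stacklevel=2
        )
        return float("nan")
    # fraction of genets with size >= x, evaluated at each distinct size
    frac = np.array([(sizes >= x).mean() for x in distinct])
    slope = np.polyfit(np.log(distinct), np.log(frac), 1)[0]
    return float(-slope)


def clone_sizes(assignment: ClonalAssignment, mask=None) -> np.ndarray:
    """Samples per MLL, optionally restricted to a boolean sample mask."""
    ids = assignment.mll_ids if mask is None else assignment.mll_ids[mask]
    return np.unique(ids, return_counts=True)[1]


def diversity_table(
    assignment: ClonalAssignment, sites: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per-site clonal summary: genets (MLLs), ramets (MLGs), lambda, beta."""
    sites = np.asarray(sites)
    rows = []
    for site in pd.unique(sites):
        mask = sites == site
        sizes = clone_sizes(assignment, mask)
        rows.append(
            {
                "site": site,
                "n_samples": int(mask.sum()),
                "n_genets": len(sizes),
                "n_ramets": len(np.unique(assignment.mlg_ids[mask])),
                "lambda": simpson_lambda(sizes),
                "pareto_beta": pareto_beta(sizes) if len(sizes) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def rarefied_ci(
    mll_by_site: dict[str, np.ndarray],
    statistic,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> pd.DataFrame:
    """Rarefied percentile interval of a clonal statistic per site.

    Each replicate draws min-site-size individuals without replacement
    from a site's MLL labels and recomputes the statistic on the resampled
    clone sizes, controlling for unequal sampling effort across sites.
    """
    if len(mll_by_site) < 2:
        raise ValueError("rarefaction needs at least two sites")
    sizes = {s: len(v) for s, v in mll_by_site.items()}
    n_rare = min(sizes.values())
    if n_rare < 2:
        raise ValueError("smallest site has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    rows = []
    for site, labels in mll_by_site.items():
        labels = np.asarray(labels)
        stats_boot = np.empty(n_boot)
        for b in range(n_boot):
            sub = rng.choice(labels, size=n_rare, replace=False)
            stats_boot[b] = statistic(np.unique(sub, return_counts=True)[1])
        finite = stats_boot[np.isfinite(stats_boot)]
        rows.append(
            {
                "site": site,
                "n_rarefied": n_rare,
                "lo": float(np.percentile(finite, lo_q)) if finite.size else np.nan,
                "hi": float(np.percentile(finite, hi_q)) if finite.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
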