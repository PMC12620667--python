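"""Genotype-environment association by dbMEM-conditioned partial RDA.

The association test asks which SNPs covary with environmental gradients
beyond what neutral population structure and spatial autocorrelation
explain. Space enters twice: least-cost marine distances between sites are
converted to distance-based Moran's eigenvector maps (dbMEMs), which are
(a) used to detrend the environmental variables and (b) included, together
with the two leading genotype principal components, as conditioning
covariates of a partial redundancy analysis (RDA) of the genotype matrix
on the detrended environment.

Candidate adaptive loci are called from the constrained-axis loadings:
each locus's Mahalanobis distance from the loading centroid (three axes by
default) is rescaled by a genomic inflation factor so the median matches
the chi-square null, converted to an upper-tail chi-square p-value, and
Bonferroni-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree

from .core import GenotypeMatrix
from .clonality import DistanceMatrix
from .popgen import pca


# ---------------------------------------------------------------- space

def least_cost_distances(
    sea_mask: np.ndarray,
    sites: np.ndarray,
    site_ids: list[str],
    cell_size: float = 1.0,
    snap_tolerance: float = 3.0,
) -> DistanceMatrix:
    """Shortest over-water path length between sites on a binary raster.

    ``sea_mask`` is a 2D array, truthy = sea; ``sites`` holds (row, col)
    grid coordinates per site. Movement is 8-connected over sea cells with
    diagonal steps weighted sqrt(2) * cell_size. Sites on land are snapped
    to the nearest sea cell within ``snap_tolerance`` cells, else an error
    is raised; a pair of sites with no over-water route raises an error
    naming the pair.
    """
    mask = np.asarray(sea_mask).astype(bool)
    nrow, ncol = mask.shape
    sea = np.flatnonzero(mask.ravel())
    node_of = -np.ones(mask.size, dtype=int)
    node_of[sea] = np.arange(len(sea))

    rows, cols, w = [], [], []
    rr, cc = np.unravel_index(sea, mask.shape)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        nr, nc_ = rr + dr, cc + dc
        ok = (nr >= 0) & (nr < nrow) & (nc_ >= 0) & (nc_ < ncol)
        ok[ok] &= mask[nr[ok], nc_[ok]]
        a = node_of[sea[ok]]
        b = node_of[nr[ok] * ncol + nc_[ok]]
        step = cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        rows += [a, b]
        cols += [b, a]
        w += [np.full(len(a), step)] * 2
    graph = sparse.csr_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(sea), len(sea)),
    )

    site_nodes = []
    for sid, (r, c) in zip(site_ids, np.asarray(sites, dtype=float)):
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        j = int(np.argmin(d2))
        if np.sqrt(d2[j]) > snap_tolerance:
            raise ValueError(
                f"site {sid} is {np.sqrt(d2[j]):.1f} cells from the nearest "
                f"sea cell, beyond the snap tolerance {snap_tolerance}"
            )
        site_nodes.append(j)

    dist = dijkstra(graph, indices=site_nodes, directed=False)[:, site_nodes]
    for i in range(len(site_ids)):
        for j in range(i + 1, len(site_ids)):
            if not np.isfinite(dist[i, j]):
                raise ValueError(
                    f"no over-water route between sites {site_ids[i]} and "
                    f"{site_ids[j]}"
                )
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(sample_ids=list(site_ids), values=dist)


@dataclass
class MemBasis:
    """dbMEM spatial basis: orthonormal eigenvectors of the Gower-centred
    truncated distance matrix, retained by spatial autocorrelation sign."""

    site_ids: list[str]
    vectors: np.ndarray  # sites x k, orthonormal columns
    eigenvalues: np.ndarray
    morans_i: np.ndarray
    truncation: float

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def expand(self, sites) -> np.ndarray:
        """Replicate site rows out to a per-sample matrix."""
        idx = {s: i for i, s in enumerate(self.site_ids)}
        return self.vectors[[idx[s] for s in np.asarray(sites)]]


def dbmem(dm: DistanceMatrix, autocorrelation: str = "positive") -> MemBasis:
    """Distance-based Moran's eigenvector maps.

    Distances are truncated at the largest minimum-spanning-tree edge t
    (which keeps the site graph connected); distances beyond t are replaced
    by 4t. The truncated matrix is Gower-centred (-1/2 D^2, double-centred)
    and eigen-decomposed. Following the standard dbMEM convention, the
    basis retains the non-degenerate eigenvectors whose Moran's I (under
    binary within-truncation neighbour weights) exceeds its expectation
    -1/(n-1), i.e. those modelling positive spatial autocorrelation;
    ``autocorrelation="all"`` keeps every positive-eigenvalue vector
    instead. Vectors are ordered by decreasing eigenvalue (broad to fine
    spatial scales).
    """
    n = dm.n
    if n < 3:
        raise ValueError("dbMEM needs at least 3 sites")
    D = dm.values
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    mst = minimum_spanning_tree(sparse.csr_matrix(D)).toarray()
    t = max(mst.max(), np.sort(np.unique(D))[1] if n > 1 else 0.0)
    Dt = np.where(D <= t, D, 4.0 * t)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-10
    nondegenerate = np.abs(vals) > tol

    # Moran's I per eigenvector under binary truncation-neighbour weights
    W = ((D <= t) & ~np.eye(n, dtype=bool)).astype(float)
    w_sum = W.sum()
    centred = vecs - vecs.mean(axis=0, keepdims=True)
    num = np.einsum("ik,ij,jk->k", centred, W, centred)
    den = (centred**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        morans = (n / w_sum) * num / den
    expected_i = -1.0 / (n - 1.0)
    if autocorrelation == "positive":
        keep = nondegenerate & (morans > expected_i) & (vals > tol)
    elif autocorrelation == "all":
        keep = vals > tol
    else:
        raise ValueError(f"unknown autocorrelation mode {autocorrelation!r}")
    return MemBasis(
        site_ids=list(dm.sample_ids),
        vectors=vecs[:, keep],
        eigenvalues=vals[keep],
        morans_i=morans[keep],
        truncation=float(t),
    )


# ------------------------------------------------------------ detrending

def detrend_env(env_values: np.ndarray, mem_columns: np.ndarray) -> np.ndarray:
    """Residuals of each environmental variable after OLS on the dbMEM
    columns (with intercept); the detrended values are orthogonal to the
    spatial basis. Collinear MEM columns are handled by least squares on
    the column space (a warning notes rank deficiency)."""
    Y = np.atleast_2d(np.asarray(env_values, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    X = np.column_stack([np.ones(len(Y)), np.asarray(mem_columns, dtype=float)])
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"spatial predictors are rank deficient ({rank} < {X.shape[1]}); "
            "collinear columns contribute nothing", stacklevel=2,
        )
    return Y - X @ coef


def screen_collinear(env_wide: pd.DataFrame, r_threshold: float = 0.9):
    """Greedy pairwise-|r| screen over environmental variables.

    Variables are visited in column order; one that correlates above the
    threshold with an already-retained variable is dropped. Returns
    (retained variable names, report DataFrame of dropped pairs).
    """
    cols = list(env_wide.columns)
    retained: list[str] = []
    dropped = []
    for c in cols:
        clash = None
        for kept in retained:
            r = np.corrcoef(env_wide[c], env_wide[kept])[0, 1]
            if abs(r) > r_threshold:
                clash = (kept, r)
                break
        if clash is None:
            retained.append(c)
        else:
            dropped.append({"dropped": c, "against": clash[0], "r": clash[1]})
    return retained, pd.DataFrame(dropped)


# ----------------------------------------------------------------- RDA

@dataclass
class RdaModel:
    axis_scores: np.ndarray  # samples x n_axes (constrained)
    loadings: np.ndarray  # loci x n_axes
    eigenvalues: np.ndarray
    r2: float
    adj_r2: float
    n_predictors: int
    n_conditions: int
    n_samples: int


def _residualize(M: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of M after OLS on [1, Z]."""
    X = (
        np.column_stack([np.ones(len(M)), Z])
        if Z is not None and Z.size
        else np.ones((len(M), 1))
    )
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def partial_rda(
    gm: GenotypeMatrix | np.ndarray,
    env: np.ndarray,
    conditions: np.ndarray | None = None,
) -> RdaModel:
    """Partial redundancy analysis of genotypes on environment.

    Genotype dosages (response) and environmental predictors are both
    residualised on the conditioning covariates, the residual genotypes are
    regressed on the residual predictors, and the constrained axes are the
    principal components of the fitted values. Locus loadings are the
    right singular vectors of the fitted matrix. R^2 is the fitted fraction
    of the conditioned genotype variance, adjusted with the Ezekiel
    correction ``1 - (1 - R^2)(n - 1)/(n - p - 1)``.
    """
    Y = gm.dosages.astype(float) if isinstance(gm, GenotypeMatrix) else np.asarray(gm, dtype=float)
    X = np.atleast_2d(np.asarray(env, dtype=float))
    if X.shape[0] == 1 and Y.shape[0] != 1:
        X = X.T
    n, L = Y.shape
    p = X.shape[1]
    q = 0 if conditions is None else np.atleast_2d(conditions).shape[1]
    if p + q + 1 >= n:
        raise ValueError(
            f"{p} predictors + {q} conditions cannot be fit with {n} samples"
        )
    Y = Y - Y.mean(axis=0, keepdims=True)
    Yr = _residualize(Y, conditions)
    Xr = _residualize(X, conditions)
    coef, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
    fitted = Xr @ coef
    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    k = min(p, n - 1, L)
    ss_tot = float((Yr**2).sum())
    ss_fit = float((fitted**2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1.0) / (n - p - 1.0)
    return RdaModel(
        axis_scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        eigenvalues=(S[:k] ** 2) / (n - 1),
        r2=r2,
        adj_r2=adj,
        n_predictors=p,
        n_conditions=q,
        n_samples=n,
    )


@dataclass
class OutlierResult:
    table: pd.DataFrame  # locus, D2, p, p_adj, outlier
    inflation_factor: float
    n_axes: int
    alpha: float

    @property
    def outlier_idx(self) -> np.ndarray:
        return np.flatnonzero(self.table["outlier"].to_numpy())


def rda_outliers(
    model: RdaModel,
    n_axes: int = 3,
    alpha: float = 0.01,
    covariance: str = "robust",
) -> OutlierResult:
    """Mahalanobis outlier test on the constrained-axis loadings.

    D^2 is each locus's squared Mahalanobis distance from the loading
    centroid under the loading covariance over ``n_axes`` axes — by
    default a robust (minimum covariance determinant) estimate so that the
    outliers being sought do not inflate the covariance themselves;
    ``covariance="empirical"`` uses the plain sample covariance (also the
    automatic fallback for small locus counts, where MCD is unstable). The
    genomic inflation factor lambda = median(D^2)/median(chi2_{n_axes})
    rescales the distances so the bulk matches the null; p-values are the
    chi-square upper tail of D^2/lambda, Bonferroni-multiplied by the
    number of loci, and loci with adjusted p < alpha are flagged.
    """
    if model.loadings.shape[1] < n_axes:
        raise ValueError(
            f"model has {model.loadings.shape[1]} constrained axes, "
            f"need {n_axes}"
        )
    Z = model.loadings[:, :n_axes]
    if covariance == "robust" and Z.shape[0] >= 20 * n_axes:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(Z)
        d2 = mcd.mahalanobis(Z)
    elif covariance in ("robust", "empirical"):
        mu = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False)
        Zc = Z - mu
        d2 = np.einsum("ij,jk,ik->i", Zc, np.linalg.inv(np.atleast_2d(cov)), Zc)
    else:
        raise ValueError(f"unknown covariance mode {covariance!r}")
    gif = float(np.median(d2) / stats.chi2.median(df=n_axes))
    pvals = stats.chi2.sf(d2 / gif, df=n_axes)
    p_adj = np.minimum(pvals * len(d2), 1.0)
    table = pd.DataFrame(
        {
            "locus": np.arange(len(d2)),
            "D2": d2,
            "p": pvals,
            "p_adj": p_adj,
            "outlier": p_adj < alpha,
        }
    )
    return OutlierResult(table=table, inflation_factor=gif, n_axes=n_axes, alpha=alpha)


# ------------------------------------------------------------- pipeline

@dataclass
class GeaResult:
    mem: MemBasis
    detrended_env: np.ndarray
    env_variables: list[str]
    model: RdaModel
    outliers: OutlierResult
    collinearity_report: pd.DataFrame


def run_gea(
    gm: GenotypeMatrix,
    sites,
    env_wide: pd.DataFrame,
    geo_distances: DistanceMatrix,
    n_axes: int = 3,
    alpha: float = 0.01,
    r_threshold: float = 0.9,
    n_structure_pcs: int = 2,
) -> GeaResult:
    """Full GEA: collinearity screen -> dbMEM -> detrend -> partial RDA ->
    Mahalanobis outliers. ``env_wide`` is a site-indexed DataFrame of
    baseline environmental values; conditioning covariates are the first
    ``n_structure_pcs`` genotype PCs plus all per-sample dbMEMs."""
    sites = np.asarray(sites)
    retained, report = screen_collinear(env_wide, r_threshold)
    env_site = env_wide[retained]
    mem = dbmem(geo_distances)
    mem_samples = mem.expand(sites)
    env_samples = env_site.loc[sites].to_numpy(dtype=float)
    env_detr = detrend_env(env_samples, mem_samples)
    pcs = pca(gm, n_axes=n_structure_pcs).scores
    conditions = np.column_stack([pcs, mem_samples])
    model = partial_rda(gm, env_detr, conditions)
    outl = rda_outliers(model, n_axes=n_axes, alpha=alpha)
    return GeaResult(
        mem=mem,
        detrended_env=env_detr,
        env_variables=retained,
        model=model,
        outliers=outl,
        collinearity_report=report,
    )
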