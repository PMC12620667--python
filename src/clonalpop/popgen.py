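"""Genetic diversity, Weir-Cockerham differentiation, and PCA structure.

Diversity per site is reported for ramets (all samples) and genets (one
representative per multilocus lineage); in highly clonal sites the two can
differ because large clones weight allele frequencies. Heterozygote excess
under clonality appears as negative F_IS.

Differentiation uses the Weir & Cockerham (1984) variance-components
estimator theta computed per pair of sites, with the per-locus a, b, c
components summed over loci before taking the ratio. Theta can be slightly
negative by construction; values are not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .clonality import ClonalAssignment


def _diploid_mask(gm: GenotypeMatrix, exclude_nondiploid: bool) -> np.ndarray:
    if exclude_nondiploid:
        return gm.ploidy == 2
    return np.ones(gm.n_samples, dtype=bool)


def diversity_stats(
    gm: GenotypeMatrix,
    sites,
    unit: str = "ramets",
    assignment: ClonalAssignment | None = None,
    min_n: int = 5,
    exclude_nondiploid: bool = True,
    polymorphic_within_site_only: bool = False,
) -> pd.DataFrame:
    """Per-site H_O, H_S and F_IS.

    Per locus, H_O is the heterozygote fraction and H_S the unbiased gene
    diversity ``2n/(2n-1) * (1 - sum p_hat^2)``; site values average over
    loci (optionally restricted to loci polymorphic within the site) and
    ``F_IS = 1 - mean(H_O)/mean(H_S)``. ``unit="genets"`` keeps the first
    sample of each multilocus lineage, which requires a clonal assignment.
    Sites with n below ``min_n`` are computed but flagged ``low_n``; a site
    with no polymorphic loci gets H_S = 0 and an undefined (NaN) F_IS.
    """
    sites = np.asarray(sites)
    if sites.shape[0] != gm.n_samples:
        raise ValueError("site labels must align with samples")
    keep = _diploid_mask(gm, exclude_nondiploid)
    if unit == "genets":
        if assignment is None:
            raise ValueError("unit='genets' requires a ClonalAssignment")
        first_of_mll = np.zeros(gm.n_samples, dtype=bool)
        # one representative per (site, MLL): clones restricted to one site
        # still count once per site where the lineage occurs
        seen = set()
        for i in range(gm.n_samples):
            key = (sites[i], assignment.mll_ids[i])
            if key not in seen:
                seen.add(key)
                first_of_mll[i] = True
        keep &= first_of_mll
    elif unit != "ramets":
        raise ValueError(f"unknown unit {unit!r}")

    rows = []
    for site in pd.unique(sites):
        mask = keep & (sites == site)
        n = int(mask.sum())
        if n < 2:
            rows.append(
                {"site": site, "unit": unit, "n": n, "H_O": np.nan,
                 "H_S": np.nan, "F_IS": np.nan, "low_n": True}
            )
            continue
        dos = gm.dosages[mask]
        p = dos.sum(axis=0) / (2.0 * n)
        het = (dos == 1).mean(axis=0)
        hs = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
        if polymorphic_within_site_only:
            poly = (p > 0) & (p < 1)
            het, hs = het[poly], hs[poly]
        ho_bar = float(het.mean()) if het.size else np.nan
        hs_bar = float(hs.mean()) if hs.size else np.nan
        fis = 1.0 - ho_bar / hs_bar if hs_bar and hs_bar > 0 else np.nan
        rows.append(
            {"site": site, "unit": unit, "n": n, "H_O": ho_bar,
             "H_S": hs_bar, "F_IS": fis, "low_n": n < min_n}
        )
    return pd.DataFrame(rows)


def _wc_components(dos_a: np.ndarray, dos_b: np.ndarray):
    """Weir-Cockerham (1984) per-locus variance components a, b, c for two
    populations of diploids given dosage matrices (samples x loci)."""
    r = 2.0
    n1, n2 = dos_a.shape[0], dos_b.shape[0]
    n_i = np.asarray([n1, n2], dtype=float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1.0)
    p_i = np.stack([dos_a.sum(0) / (2 * n1), dos_b.sum(0) / (2 * n2)])
    h_i = np.stack([(dos_a == 1).mean(0), (dos_b == 1).mean(0)])
    pbar = (n_i[:, None] * p_i).sum(0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(0) / ((r - 1.0) * nbar)
    hbar = (n_i[:, None] * h_i).sum(0) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def pairwise_fst(
    gm: GenotypeMatrix, sites, exclude_nondiploid: bool = True
) -> pd.DataFrame:
    """Pairwise Weir-Cockerham theta between sites.

    Per pair, the per-locus a/b/c variance components are summed over loci
    and theta = sum(a) / sum(a+b+c); loci monomorphic across the pair
    contribute zero to both sums. Returns a square DataFrame (NaN
    diagonal); a fully monomorphic pair is NaN.
    """
    sites = np.asarray(sites)
    keep = _diploid_mask(gm, exclude_nondiploid)
    site_list = [s for s in pd.unique(sites) if (keep & (sites == s)).sum() >= 2]
    k = len(site_list)
    if k < 2:
        raise ValueError("pairwise F_ST needs >= 2 sites with n >= 2")
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            da = gm.dosages[keep & (sites == site_list[i])]
            db = gm.dosages[keep & (sites == site_list[j])]
            a, b, c = _wc_components(da.astype(float), db.astype(float))
            denom = (a + b + c).sum()
            out[i, j] = out[j, i] = a.sum() / denom if denom > 0 else np.nan
    return pd.DataFrame(out, index=site_list, columns=site_list)


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x axes
    explained_variance_ratio: np.ndarray
    n_axes: int


def pca(gm: GenotypeMatrix, n_axes: int = 3) -> PcaResult:
    """PCA of column-centred dosages via SVD. Scores are U * S; explained
    variance fractions are non-increasing. Requests beyond the matrix rank
    are truncated with a warning."""
    if gm.missing_mask.any():
        raise ValueError("PCA requires complete data; filter first")
    X = gm.dosages.astype(float)
    X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    tol = S.max() * max(X.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if n_axes > rank:
        import warnings

        warnings.warn(
            f"requested {n_axes} axes but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_axes = rank
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else var
    return PcaResult(
        sample_ids=list(gm.sample_ids),
        scores=U[:, :n_axes] * S[:n_axes],
        explained_variance_ratio=evr[:n_axes],
        n_axes=n_axes,
    )
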