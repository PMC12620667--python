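"""Geometric genomic offset from latent-factor environmental effect sizes.

The offset predicts how far a population's adaptive allele frequencies
would have to move to track an environmental change. Per-locus effect
sizes on the (standardized) environmental variables are estimated from the
candidate adaptive genotypes with a latent-factor adjustment for neutral
structure; the offset between a baseline and a future environment is then
the mean squared predicted allele-frequency displacement,

    offset(x, x*) = (1/L) * || B (x* - x) ||^2 ,

a geometric quantity comparable only within one analysis. Effects and
latent factors are estimated by alternating least squares: regress
genotypes on the environment, take the top-K singular subspace of
``Y - X B_hat`` (not the OLS residual, which is orthogonal to X by
construction and would make the adjustment a no-op) as latent factors,
re-estimate effects jointly on [environment, factors], and iterate to
convergence. Structure independent of the environment is removed this
way; structure collinear with the environment is inherently
unidentifiable and is absorbed into the effects (documented limitation).
With K = 0 the estimator is plain multivariate OLS and recovers noiseless
linear effects exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix


@dataclass
class EffectModel:
    """Per-locus environmental effect sizes with the baseline scaling."""

    effects: np.ndarray  # loci x variables
    variables: list[str]
    env_mean: np.ndarray
    env_sd: np.ndarray
    n_factors: int

    def standardize(self, env: np.ndarray) -> np.ndarray:
        """Express environment in baseline units (baseline mean/sd)."""
        return (np.asarray(env, dtype=float) - self.env_mean) / self.env_sd


def fit_effects(
    gm: GenotypeMatrix | np.ndarray,
    env_baseline: np.ndarray,
    n_factors: int = 4,
    variables: list[str] | None = None,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> EffectModel:
    """Estimate loci x variables effect sizes with latent-factor adjustment.

    ``env_baseline`` is samples x variables on the original scale; it is
    standardized on its own mean/sd and the scaling is stored so future
    environments are expressed in baseline units. ``n_factors`` (K) latent
    factors absorb environment-independent structure via alternating least
    squares; K = 0 reduces to plain multivariate OLS. ``ridge`` adds an L2
    penalty on the joint design.
    """
    Y = gm.dosages.astype(float) if isinstance(gm, GenotypeMatrix) else np.asarray(gm, dtype=float)
    X = np.atleast_2d(np.asarray(env_baseline, dtype=float))
    if X.shape[0] == 1 and Y.shape[0] != 1:
        X = X.T
    n, L = Y.shape
    if n_factors >= n:
        raise ValueError(f"K = {n_factors} latent factors require > K samples")
    mean, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant environmental variable cannot be standardized")
    Xs = (X - mean) / sd
    Yc = Y - Y.mean(axis=0, keepdims=True)
    d = Xs.shape[1]

    def solve(design: np.ndarray) -> np.ndarray:
        if ridge > 0:
            XtX = design.T @ design + ridge * np.eye(design.shape[1])
            return np.linalg.solve(XtX, design.T @ Yc)
        return np.linalg.lstsq(design, Yc, rcond=None)[0]

    base = np.column_stack([np.ones(n), Xs])
    if n_factors == 0:
        B = solve(base)[1 : 1 + d].T
    else:
        # alternating least squares, factors initialised from the raw
        # (unadjusted) matrix: Y - Xs B_hat keeps X-correlated factor
        # structure, unlike the OLS residual which is orthogonal to X and
        # would freeze B at its unadjusted value
        B = np.zeros((L, d))
        for _ in range(max_iter):
            stripped = Yc - Xs @ B.T
            U, _, _ = np.linalg.svd(stripped, full_matrices=False)
            design = np.column_stack([base, U[:, :n_factors]])
            coef = solve(design)
            B_new = coef[1 : 1 + d].T
            delta = np.linalg.norm(B_new - B) / max(np.linalg.norm(B), 1e-12)
            B = B_new
            if delta < tol:
                break
    # B is loci x variables, on the standardized scale
    return EffectModel(
        effects=B,
        variables=list(variables) if variables is not None else [f"v{i}" for i in range(d)],
        env_mean=mean,
        env_sd=sd,
        n_factors=n_factors,
    )


@dataclass
class OffsetResult:
    per_sample: pd.DataFrame  # sample_id, site, offset
    per_site: pd.DataFrame  # site, offset (mean over samples)


def genetic_offset(
    model: EffectModel,
    env_baseline: np.ndarray,
    env_future: np.ndarray,
    sample_ids: list[str] | None = None,
    sites=None,
) -> OffsetResult:
    """Geometric genomic offset per sample and averaged per site.

    Both scenarios must share the model's variables; each is standardized
    with the stored baseline scaling and the offset is
    ``(1/L) ||B dx||^2`` with ``dx`` the standardized change. Zero change
    gives zero offset; the measure is relative within one analysis.
    """
    xb = np.atleast_2d(np.asarray(env_baseline, dtype=float))
    xf = np.atleast_2d(np.asarray(env_future, dtype=float))
    if xb.shape != xf.shape:
        raise ValueError("baseline and future environments differ in shape")
    if xb.shape[1] != model.effects.shape[1]:
        raise ValueError(
            f"environment has {xb.shape[1]} variables, model expects "
            f"{model.effects.shape[1]}"
        )
    dx = model.standardize(xf) - model.standardize(xb)
    L = model.effects.shape[0]
    disp = dx @ model.effects.T  # samples x loci predicted displacement
    offsets = (disp**2).sum(axis=1) / L
    n = len(offsets)
    per_sample = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else np.arange(n),
            "site": np.asarray(sites) if sites is not None else ["all"] * n,
            "offset": offsets,
        }
    )
    per_site = (
        per_sample.groupby("site", sort=False)["offset"].mean().reset_index()
    )
    return OffsetResult(per_sample=per_sample, per_site=per_site)
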