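"""Spatial predictors, partial RDA and outlier calling.

The partial-RDA implementation is cross-checked against vegan's rda()
(run through Rscript) on a small random problem; spatial and outlier
steps are checked against hand-built rasters and null simulations.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd

from clonalpop.clonality import DistanceMatrix
from clonalpop.core import GenotypeMatrix
from clonalpop.gea import (
    RdaModel,
    dbmem,
    detrend_env,
    least_cost_distances,
    partial_rda,
    rda_outliers,
    run_gea,
    screen_collinear,
)
from clonalpop.popgen import pca
from clonalpop.simulate import SimConfig, simulate_dataset


# ------------------------------------------------------------ least cost

def test_open_sea_distance_close_to_euclidean():
    mask = np.ones((20, 20), bool)
    sites = np.array([[2.0, 2.0], [14.0, 18.0]])
    dm = least_cost_distances(mask, sites, ["a", "b"])
    euclid = np.hypot(12, 16)
    # 8-connected grid paths overshoot the straight line by < 9%
    assert euclid <= dm.values[0, 1] <= euclid * 1.09


def test_wall_with_gap_routes_through_gap():
    mask = np.ones((11, 11), bool)
    mask[:, 5] = False
    mask[5, 5] = True  # single gap at row 5
    sites = np.array([[5.0, 0.0], [5.0, 10.0]])
    dm = least_cost_distances(mask, sites, ["w", "e"])
    # straight corridor through the gap: 10 horizontal steps
    assert dm.values[0, 1] == pytest.approx(10.0)
    sites_off = np.array([[0.0, 0.0], [0.0, 10.0]])
    dm2 = least_cost_distances(mask, sites_off, ["nw", "ne"])
    # must detour to row 5 and back: 5 diagonals each way via the gap
    assert dm2.values[0, 1] == pytest.approx(10 * np.sqrt(2))


def test_site_on_land_beyond_tolerance_errors():
    mask = np.zeros((10, 10), bool)
    mask[:2, :] = True
    with pytest.raises(ValueError, match="snap tolerance"):
        least_cost_distances(mask, np.array([[9.0, 5.0]]), ["far"])


def test_disconnected_sites_error_names_pair():
    mask = np.ones((6, 6), bool)
    mask[:, 3] = False  # impassable wall
    sites = np.array([[2.0, 0.0], [2.0, 5.0]])
    with pytest.raises(ValueError, match="no over-water route.*west.*east"):
        least_cost_distances(mask, sites, ["west", "east"])


# ----------------------------------------------------------------- dbMEM

def collinear_sites(n=6, spacing=10.0):
    xy = np.column_stack([np.zeros(n), spacing * np.arange(n)])
    D = ssd.squareform(ssd.pdist(xy))
    return DistanceMatrix([f"s{i}" for i in range(n)], D)


def test_dbmem_matches_pcoa_oracle():
    """Eigenvectors equal an independent principal-coordinate analysis of
    the truncated distance matrix (scikit-bio), up to sign."""
    skbio = pytest.importorskip("skbio")
    dm = collinear_sites()
    mem = dbmem(dm, autocorrelation="all")
    # independent truncation + PCoA
    t = mem.truncation
    Dt = np.where(dm.values <= t, dm.values, 4 * t)
    np.fill_diagonal(Dt, 0.0)
    res = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(Dt, dm.sample_ids))
    eigs = res.eigvals.to_numpy()[: mem.k]
    assert np.allclose(np.sort(eigs), np.sort(mem.eigenvalues), rtol=1e-8)
    V = res.samples.to_numpy()[:, : mem.k]
    Vn = V / np.linalg.norm(V, axis=0)
    for j in range(mem.k):
        dots = np.abs(Vn.T @ mem.vectors[:, j])
        assert dots.max() > 1 - 1e-8  # same axis up to sign/order


def test_dbmem_orthonormal_columns():
    mem = dbmem(collinear_sites(8))
    V = mem.vectors
    assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)


def test_dbmem_moran_positive_subset_of_all():
    dm = collinear_sites(10)
    pos = dbmem(dm, autocorrelation="positive")
    allv = dbmem(dm, autocorrelation="all")
    assert 0 < pos.k <= allv.k
    assert (pos.morans_i > -1 / 9).all()


def test_dbmem_permutation_equivariance():
    dm = collinear_sites(7)
    perm = np.array([3, 1, 6, 0, 2, 5, 4])
    dmp = DistanceMatrix(
        [dm.sample_ids[i] for i in perm], dm.values[np.ix_(perm, perm)]
    )
    m1, m2 = dbmem(dm), dbmem(dmp)
    assert m1.k == m2.k
    # rows permute identically (up to per-axis sign)
    for j in range(m1.k):
        v1, v2 = m1.vectors[perm, j], m2.vectors[:, j]
        assert np.allclose(v1, v2, atol=1e-9) or np.allclose(v1, -v2, atol=1e-9)


def test_dbmem_needs_three_sites():
    with pytest.raises(ValueError, match="3 sites"):
        dbmem(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


# ------------------------------------------------------------- detrending

def test_detrend_removes_exact_linear_dependence():
    mem = dbmem(collinear_sites(6))
    env = 2.0 + 3.0 * mem.vectors[:, 0]
    resid = detrend_env(env, mem.vectors)
    assert np.allclose(resid, 0.0, atol=1e-10)


def test_detrend_orthogonal_env_is_centred_env():
    rng = np.random.default_rng(0)
    mem = dbmem(collinear_sites(8))
    raw = rng.normal(size=8)
    # orthogonalize against MEMs and the intercept
    Q = np.column_stack([np.ones(8) / np.sqrt(8), mem.vectors])
    env = raw - Q @ (Q.T @ raw)
    resid = detrend_env(env, mem.vectors).ravel()
    assert np.allclose(resid, env - env.mean(), atol=1e-10)


def test_detrend_matches_hat_matrix_oracle():
    rng = np.random.default_rng(1)
    mem = dbmem(collinear_sites(6))
    env = rng.normal(size=(6, 2))
    X = np.column_stack([np.ones(6), mem.vectors])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    expected = env - H @ env
    assert np.allclose(detrend_env(env, mem.vectors), expected, atol=1e-10)


def test_detrend_residuals_orthogonal_to_mems():
    rng = np.random.default_rng(2)
    mem = dbmem(collinear_sites(9))
    resid = detrend_env(rng.normal(size=(9, 3)), mem.vectors)
    assert np.allclose(mem.vectors.T @ resid, 0.0, atol=1e-9)


# ---------------------------------------------------------- collinearity

def test_collinearity_screen_drops_redundant_variable():
    rng = np.random.default_rng(3)
    a = rng.normal(size=40)
    df = pd.DataFrame({"temp": a, "oxygen": -a + rng.normal(0, 0.05, 40),
                       "vel": rng.normal(size=40)})
    retained, report = screen_collinear(df, 0.9)
    assert retained == ["temp", "vel"]
    assert report.iloc[0]["dropped"] == "oxygen"
    assert report.iloc[0]["r"] < -0.9


# ------------------------------------------------------------------- RDA

def test_orthogonal_predictors_give_zero_r2():
    rng = np.random.default_rng(4)
    n = 40
    Y = rng.normal(size=(n, 30))
    X = rng.normal(size=(n, 3))
    # force exact orthogonality of X columns to Y columns
    Q, _ = np.linalg.qr(Y - Y.mean(0))
    X = X - Q @ (Q.T @ X)
    m = partial_rda(Y, X, None)
    assert m.r2 == pytest.approx(0.0, abs=1e-10)
    assert m.adj_r2 <= 0.0


def test_exact_linear_map_gives_adjusted_r2_one():
    rng = np.random.default_rng(5)
    n, p, L = 25, 2, 15
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, L))
    m = partial_rda(X @ B, X, None)
    assert m.r2 == pytest.approx(1.0, abs=1e-10)
    assert m.adj_r2 == pytest.approx(1.0, abs=1e-10)


def test_adjusted_r2_decreases_with_irrelevant_predictors():
    rng = np.random.default_rng(6)
    n = 50
    X = rng.normal(size=(n, 2))
    Y = X @ rng.normal(size=(2, 40)) + rng.normal(size=(n, 40))
    adj = []
    for extra in (0, 4, 8):
        Xe = np.column_stack([X, rng.normal(size=(n, extra))]) if extra else X
        adj.append(partial_rda(Y, Xe, None).adj_r2)
    assert adj[0] > adj[1] > adj[2]


def test_too_many_predictors_rejected():
    rng = np.random.default_rng(7)
    with pytest.raises(ValueError, match="predictors"):
        partial_rda(rng.normal(size=(5, 10)), rng.normal(size=(5, 6)), None)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_rda_matches_vegan(tmp_path):
    """Independent oracle: vegan's rda() agrees on R^2, adjusted R^2 and
    constrained eigenvalue proportions."""
    rng = np.random.default_rng(8)
    n, L, p = 30, 40, 3
    Y = rng.integers(0, 3, size=(n, L)).astype(float)
    X = rng.normal(size=(n, p))
    np.savetxt(tmp_path / "Y.tsv", Y, delimiter="\t")
    np.savetxt(tmp_path / "X.tsv", X, delimiter="\t")
    script = tmp_path / "rda.R"
    script.write_text(
        'Y <- as.matrix(read.table("Y.tsv"))\n'
        'X <- as.matrix(read.table("X.tsv"))\n'
        "suppressMessages(library(vegan))\n"
        "m <- rda(Y ~ X)\n"
        'cat(RsquareAdj(m)$r.squared, RsquareAdj(m)$adj.r.squared,\n'
        '    m$CCA$eig / sum(m$CCA$eig), sep="\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", script.name],
        cwd=tmp_path, capture_output=True, text=True, timeout=120,
    )
    assert out.returncode == 0, out.stderr
    vals = [float(x) for x in out.stdout.split()]
    m = partial_rda(Y, X, None)
    assert m.r2 == pytest.approx(vals[0], rel=1e-6)
    assert m.adj_r2 == pytest.approx(vals[1], rel=1e-5)
    assert np.allclose(m.eigenvalues / m.eigenvalues.sum(), vals[2:5], rtol=1e-6)


# --------------------------------------------------------------- outliers

def null_model(L=5000, seed=0, k=3):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(L, k))
    return RdaModel(
        axis_scores=np.zeros((10, k)), loadings=Z, eigenvalues=np.ones(k),
        r2=0.0, adj_r2=0.0, n_predictors=k, n_conditions=0, n_samples=10,
    )


def test_null_loadings_calibrated_inflation_and_no_outliers():
    out = rda_outliers(null_model())
    assert 0.9 < out.inflation_factor < 1.1
    assert out.table["outlier"].sum() <= 1


def test_single_extreme_locus_flagged():
    m = null_model(L=2000, seed=1)
    m.loadings[0] *= 10.0
    out = rda_outliers(m)
    assert out.table.loc[0, "outlier"]
    assert out.table["outlier"].sum() <= 2


def test_alpha_zero_flags_nothing():
    m = null_model(L=1000, seed=2)
    m.loadings[0] *= 10.0
    assert rda_outliers(m, alpha=0.0).table["outlier"].sum() == 0


def test_fewer_axes_than_requested_errors():
    m = null_model(k=2)
    with pytest.raises(ValueError, match="axes"):
        rda_outliers(m, n_axes=3)


def test_empirical_covariance_option():
    out = rda_outliers(null_model(L=1000, seed=3), covariance="empirical")
    assert 0.8 < out.inflation_factor < 1.2


# ------------------------------------------------- end-to-end conditioning

@pytest.fixture(scope="module")
def gea_sim():
    cfg = SimConfig(n_sites=10, samples_per_site=15, n_loci=3000,
                    n_adaptive_loci=40, somatic_rate=0.0,
                    genet_geometric_p=1.0, seed=0)
    ds = simulate_dataset(cfg)
    sites = ds.truth.samples["site"].to_numpy()
    env_wide = ds.env.pivot(index="site", columns="variable",
                            values="baseline_value")
    order = sorted(env_wide.index)
    coords = np.array([[50 + 0.15 * i, -5 + 0.35 * i] for i in range(len(order))])
    geo = DistanceMatrix(order, ssd.squareform(ssd.pdist(coords * 111.0)))
    return ds, sites, env_wide, geo


def test_conditioning_immunises_against_structure_confounder(gea_sim):
    """Planting a strong artificial site-structure signal in neutral loci
    changes the unconditioned outlier set but leaves the conditioned one
    nearly unchanged (overlap >= 90%)."""
    ds, sites, env_wide, geo = gea_sim
    gm = ds.genotypes_diploid
    rng = np.random.default_rng(99)
    neutral = np.flatnonzero(~ds.truth.loci["adaptive"])
    conf = rng.choice(neutral, 400, replace=False)
    dos2 = gm.dosages.copy()
    half = np.isin(sites, sorted(set(sites))[:5])
    dos2[np.ix_(half, conf)] = np.clip(dos2[np.ix_(half, conf)] + 1, 0, 2)
    gm2 = GenotypeMatrix(list(gm.sample_ids), gm.loci.copy(), dos2)

    cond1 = set(run_gea(gm, sites, env_wide, geo).outliers.outlier_idx)
    cond2 = set(run_gea(gm2, sites, env_wide, geo).outliers.outlier_idx)
    assert len(cond1 & cond2) / max(len(cond1), 1) >= 0.9
    assert len(cond2 & set(conf)) <= 2  # confounder not mistaken for signal

    env_s = env_wide.loc[sites].to_numpy(float)
    un1 = set(rda_outliers(partial_rda(gm, env_s, None)).table.query("outlier").locus)
    un2 = set(rda_outliers(partial_rda(gm2, env_s, None)).table.query("outlier").locus)
    assert len(un2 & set(conf)) > 5  # unconditioned analysis is fooled
    assert un1 != un2


def test_planted_loci_load_on_constrained_axes(gea_sim):
    ds, sites, env_wide, geo = gea_sim
    res = run_gea(ds.genotypes_diploid, sites, env_wide, geo)
    adaptive = np.flatnonzero(ds.truth.loci["adaptive"])
    load = np.abs(res.model.loadings[:, 0])
    assert np.median(load[adaptive]) > np.median(np.delete(load, adaptive))
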