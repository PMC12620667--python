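"""Clonal assignment and diversity statistics against brute-force oracles."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from clonalpop.clonality import (
    ClonalAssignment,
    DistanceMatrix,
    assign_mll,
    candidate_thresholds,
    clone_sizes,
    diversity_table,
    hamming_distances,
    pareto_beta,
    predict_clone_threshold,
    rarefied_ci,
    simpson_lambda,
)
from conftest import make_gm


def dm_from(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix([f"s{i}" for i in range(len(values))], values)


# ------------------------------------------------------------- distances

def test_identical_samples_distance_zero():
    gm = make_gm(np.tile([0, 1, 2, 1], (3, 1)))
    dm = hamming_distances(gm)
    assert np.allclose(dm.values, 0.0)


def test_maximal_distance_is_one():
    gm = make_gm(np.array([[0, 0], [2, 2]]))
    assert hamming_distances(gm).values[0, 1] == pytest.approx(1.0)


def test_hamming_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    dos = rng.integers(0, 3, size=(4, 6))
    gm = make_gm(dos)
    dm = hamming_distances(gm)
    for i in range(4):
        for j in range(4):
            expected = sum(abs(int(dos[i, l]) - int(dos[j, l])) for l in range(6))
            assert dm.values[i, j] == pytest.approx(expected / (2 * 6), abs=1e-12)


def test_missing_data_refused():
    from clonalpop.core import MISSING

    gm = make_gm(np.array([[0, MISSING], [1, 1]]))
    with pytest.raises(ValueError, match="filter"):
        hamming_distances(gm)


# ------------------------------------------------------------ assignment

def test_threshold_zero_equals_mlg_partition():
    d = np.array(
        [
            [0.0, 0.0, 0.2],
            [0.0, 0.0, 0.2],
            [0.2, 0.2, 0.0],
        ]
    )
    a = assign_mll(dm_from(d), 0.0)
    assert a.n_mll == a.n_mlg == 2
    assert a.mll_ids[0] == a.mll_ids[1] != a.mll_ids[2]


def test_threshold_above_max_gives_single_lineage():
    rng = np.random.default_rng(1)
    gm = make_gm(rng.integers(0, 3, size=(5, 20)))
    dm = hamming_distances(gm)
    a = assign_mll(dm, dm.values.max() + 0.01)
    assert a.n_mll == 1


def test_negative_threshold_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        assign_mll(dm_from(np.zeros((2, 2))), -0.1)


def test_mll_refines_to_mlg():
    """Samples sharing an MLG (distance 0) always share an MLL."""
    rng = np.random.default_rng(2)
    base = rng.integers(0, 3, size=(3, 30))
    dos = np.vstack([base, base[0], base[1]])  # clones of samples 0 and 1
    dm = hamming_distances(make_gm(dos))
    for thr in (0.0, 0.1, 0.5):
        a = assign_mll(dm, thr)
        assert a.mll_ids[0] == a.mll_ids[3]
        assert a.mll_ids[1] == a.mll_ids[4]


def test_assignment_matches_scipy_average_linkage():
    """Independent oracle: scipy's average-linkage dendrogram cut at the
    same threshold yields the same partition. Distances are continuous
    (tie-free): with exactly tied linkages the two implementations may pick
    different, equally valid merge orders."""
    rng = np.random.default_rng(3)
    for trial in range(10):
        flat = rng.uniform(0.05, 1.0, size=8 * 7 // 2)
        dm = dm_from(squareform(flat))
        Z = linkage(squareform(dm.values, checks=False), method="average")
        heights = np.unique(Z[:, 2])
        cuts = np.concatenate([[heights[0] / 2], (heights[:-1] + heights[1:]) / 2,
                               [heights[-1] + 0.1]])
        for thr in cuts:
            ours = assign_mll(dm, thr).mll_ids
            scipy_labels = fcluster(Z, t=thr, criterion="distance")
            # same partition up to relabelling
            pairs_ours = (ours[:, None] == ours[None, :])
            pairs_scipy = (scipy_labels[:, None] == scipy_labels[None, :])
            assert np.array_equal(pairs_ours, pairs_scipy), (trial, thr)


def test_monotone_coarsening_in_threshold():
    rng = np.random.default_rng(4)
    dos = rng.integers(0, 3, size=(10, 30))
    dm = hamming_distances(make_gm(dos))
    counts = [assign_mll(dm, t).n_mll for t in np.linspace(0, 1, 25)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------- candidate thresholds

def test_two_samples_single_candidate():
    d = np.array([[0.0, 0.1], [0.1, 0.0]])
    assert candidate_thresholds(dm_from(d)).tolist() == [0.1]


def test_equidistant_triplet_single_candidate():
    d = np.full((3, 3), 0.2)
    np.fill_diagonal(d, 0.0)
    assert candidate_thresholds(dm_from(d)).tolist() == [pytest.approx(0.2)]


def test_all_identical_no_candidates():
    assert len(candidate_thresholds(dm_from(np.zeros((4, 4))))) == 0


def test_single_sample_no_candidates():
    assert len(candidate_thresholds(dm_from(np.zeros((1, 1))))) == 0


# -------------------------------------------------------- threshold choice

def test_threshold_prediction_rule_by_hand():
    # prefix = first ceil(0.5*4)=2 candidates [0.01, 0.02]; largest (only)
    # gap is 0.01 wide; midpoint 0.015
    assert predict_clone_threshold([0.01, 0.02, 0.10, 0.50], 0.5) == pytest.approx(0.015)


def test_two_candidates_full_fraction_is_midpoint():
    assert predict_clone_threshold([0.2, 0.6], 1.0) == pytest.approx(0.4)


def test_no_candidates_returns_zero_with_warning():
    with pytest.warns(UserWarning, match="fewer than two"):
        assert predict_clone_threshold([]) == 0.0


def test_predicted_threshold_separates_distance_modes():
    """On clonal simulations the predicted cut-off lies between the
    within-genet and between-genet distance modes."""
    from clonalpop.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_sites=1, samples_per_site=18, n_loci=3000,
                    somatic_rate=1e-3, n_adaptive_loci=0,
                    genet_sizes=[[4, 3, 2, 2, 2, 1, 1, 1, 1, 1]], seed=13)
    ds = simulate_dataset(cfg)
    dm = hamming_distances(ds.genotypes_diploid)
    thr = predict_clone_threshold(candidate_thresholds(dm))
    genet = ds.truth.samples["genet_id"].to_numpy()
    same = genet[:, None] == genet[None, :]
    iu = np.triu_indices(dm.n, 1)
    within = dm.values[iu][same[iu]]
    between = dm.values[iu][~same[iu]]
    assert within.max() < thr < between.min()


# ------------------------------------------------------------- diversity

def test_simpson_lambda_examples():
    assert simpson_lambda([5]) == 0.0
    assert simpson_lambda([2, 1, 1]) == pytest.approx(1 - 6 / 16, abs=1e-12)
    n = 37
    assert simpson_lambda([1] * n) == pytest.approx(1 - 1 / n, abs=1e-12)


def test_simpson_rejects_bad_sizes():
    with pytest.raises(ValueError):
        simpson_lambda([2, 0])
    assert np.isnan(simpson_lambda([]))


def test_pareto_beta_all_singletons_infinite():
    assert pareto_beta([1, 1, 1, 1]) == float("inf")


def test_pareto_beta_matches_ols_oracle():
    """Independent log-log OLS on the reverse cumulative distribution."""
    sizes = np.array([4, 2, 2, 1, 1])
    distinct = np.unique(sizes)
    y = [np.mean(sizes >= x) for x in distinct]
    X = np.column_stack([np.ones(len(distinct)), np.log(distinct)])
    slope = np.linalg.lstsq(X, np.log(y), rcond=None)[0][1]
    assert pareto_beta(sizes) == pytest.approx(-slope, abs=1e-12)


def test_pareto_beta_lower_for_skewed_configurations():
    assert pareto_beta([8, 1, 1, 1, 1]) < pareto_beta([3, 3, 2, 2, 2])


def test_pareto_beta_single_distinct_size_undefined():
    with pytest.warns(UserWarning, match="distinct"):
        assert np.isnan(pareto_beta([2, 2]))


def test_diversity_invariant_to_relabelling_and_order():
    rng = np.random.default_rng(5)
    sizes = rng.integers(1, 6, size=8)
    perm = rng.permutation(sizes)
    assert simpson_lambda(sizes) == pytest.approx(simpson_lambda(perm), abs=1e-15)
    assert pareto_beta(sizes) == pytest.approx(pareto_beta(perm), abs=1e-12)


def test_diversity_table_columns(small_sim):
    dm = hamming_distances(small_sim.genotypes_diploid)
    a = assign_mll(dm, predict_clone_threshold(candidate_thresholds(dm)))
    table = diversity_table(a, small_sim.truth.samples["site"])
    assert set(table.columns) >= {"site", "n_genets", "n_ramets", "lambda", "pareto_beta"}
    assert (table["n_genets"] <= table["n_samples"]).all()


# ------------------------------------------------------------ rarefaction

def test_rarefaction_deterministic_under_seed():
    mlls = {
        "A": np.array([0, 0, 1, 2, 3]),
        "B": np.array([4, 4, 4, 5, 6, 7, 8]),
    }
    a = rarefied_ci(mlls, simpson_lambda, n_boot=200, seed=11)
    b = rarefied_ci(mlls, simpson_lambda, n_boot=200, seed=11)
    assert a.equals(b)


def test_rarefaction_interval_covers_point_for_equal_sites():
    """With equal site sizes rarefaction draws the full site every time, so
    the interval collapses onto the point estimate."""
    mlls = {"A": np.array([0, 0, 1, 2]), "B": np.array([3, 4, 5, 5])}
    ci = rarefied_ci(mlls, simpson_lambda, n_boot=50, seed=0)
    for site, labels in mlls.items():
        point = simpson_lambda(np.unique(labels, return_counts=True)[1])
        row = ci[ci["site"] == site].iloc[0]
        assert row["lo"] == pytest.approx(point)
        assert row["hi"] == pytest.approx(point)


def test_rarefaction_needs_two_sites_and_min_size():
    with pytest.raises(ValueError, match="two sites"):
        rarefied_ci({"A": np.array([0, 1])}, simpson_lambda)
    with pytest.raises(ValueError, match="fewer than 2"):
        rarefied_ci(
            {"A": np.array([0]), "B": np.array([1, 2])}, simpson_lambda
        )
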