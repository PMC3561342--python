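import numpy as np
import pytest

from hkatlas.core import InvalidInputError, round_half_up
from hkatlas.reference import (NORMAL_TISSUE_TRILEVEL, UNIFIED_HIGH_RPKM,
                               UNIFIED_LOW_RPKM)
from hkatlas.trilevel import (dp_optimal_objective, extract_thresholds, transform,
                              trilevel_sample, trilevel_table, unify_thresholds,
                              weighted_kmedians_1d)
from tests.conftest import make_matrix


def test_transform_is_monotone_and_anchored():
    assert transform(1.0) == pytest.approx(1.0)  # log2(1 + 1)
    assert transform(3.0) == pytest.approx(2.0)
    x = np.linspace(0.01, 100, 500)
    assert (np.diff(transform(x)) > 0).all()
    with pytest.raises(InvalidInputError):
        transform([1.0, 0.0])


def test_three_well_separated_groups_recovered():
    x = np.concatenate([
        np.linspace(0.3, 0.9, 10),     # LEG
        np.linspace(4.0, 9.0, 10),     # MEG
        np.linspace(40.0, 90.0, 10),   # HEG
    ])
    state = weighted_kmedians_1d(x)
    assert state.cluster_weight(0) == 10
    assert state.cluster_weight(1) == 10
    assert state.cluster_weight(2) == 10
    low, high = extract_thresholds(state)
    assert 0.9 < low < 4.0
    assert 9.0 < high < 40.0
    # contiguity: labels are non-decreasing along sorted x
    assert (np.diff(state.labels) >= 0).all()


def test_weights_matter_hand_case():
    """A value repeated many times must pull the weighted median onto it."""
    x = [1.0, 2.0, 3.0, 10.0, 20.0, 100.0]
    w = [1, 50, 1, 1, 1, 1]
    state = weighted_kmedians_1d(x, weights=w, k=3)
    assert 2.0 in state.centroids  # the heavy point is a centroid
    # aggregation: duplicating the point explicitly is equivalent
    x2 = [1.0] + [2.0] * 50 + [3.0, 10.0, 20.0, 100.0]
    state2 = weighted_kmedians_1d(x2, k=3)
    np.testing.assert_allclose(state.centroids, state2.centroids)
    assert state.objective == pytest.approx(state2.objective)


def test_centroids_are_data_values():
    rng = np.random.default_rng(2)
    x = rng.lognormal(1.0, 1.5, 200)
    state = weighted_kmedians_1d(x, seed=0, max_restarts=5)
    for c in state.centroids:
        assert c in state.x


def test_matches_dp_oracle_on_small_instances():
    """Converged k-medians objective equals the exact contiguous-partition
    optimum on most small instances (with restarts)."""
    rng = np.random.default_rng(10)
    hits = 0
    n_trials = 50
    for _ in range(n_trials):
        m = int(rng.integers(6, 40))
        x = rng.lognormal(rng.normal(1.0, 0.5), rng.uniform(0.5, 2.0), m)
        x = np.maximum(x, 1e-6)
        w = rng.integers(1, 6, m)
        opt = dp_optimal_objective(x, weights=w)
        got = weighted_kmedians_1d(x, weights=w, seed=1, max_restarts=20).objective
        assert got >= opt - 1e-9  # never below the true optimum
        if got <= opt * 1.001 + 1e-12:
            hits += 1
    assert hits >= 0.95 * n_trials


def test_dp_oracle_hand_value():
    # points 1,3 / 7 / 15,31 -> transformed 1,2 / 3 / 4,5; optimal segments
    # {1,2},{3},{4,5} cost (0.5+0.5) + 0 + (0.5+0.5) with unit weights = 2
    x = [1.0, 3.0, 7.0, 15.0, 31.0]
    assert dp_optimal_objective(x, k=3) == pytest.approx(2.0)
    state = weighted_kmedians_1d(x, k=3, seed=0, max_restarts=5)
    assert state.objective == pytest.approx(2.0)


def test_raw_distance_space_changes_geometry():
    # in raw space the large gap dominates; in log space the small values split
    x = [1.0, 2.0, 4.0, 1000.0, 2000.0, 4000.0]
    raw = weighted_kmedians_1d(x, distance_space="raw", seed=0, max_restarts=10)
    tr = weighted_kmedians_1d(x, distance_space="transformed", seed=0, max_restarts=10)
    assert raw.distance_space == "raw" and tr.distance_space == "transformed"
    assert dp_optimal_objective(x, distance_space="raw") == pytest.approx(raw.objective)
    assert dp_optimal_objective(x) == pytest.approx(tr.objective)


def test_deterministic_given_seed():
    rng = np.random.default_rng(5)
    x = rng.lognormal(1, 1, 300)
    a = weighted_kmedians_1d(x, seed=42, max_restarts=8)
    b = weighted_kmedians_1d(x, seed=42, max_restarts=8)
    np.testing.assert_array_equal(a.labels, b.labels)
    assert a.objective == b.objective


def test_too_few_distinct_values_rejected():
    with pytest.raises(InvalidInputError):
        weighted_kmedians_1d([1.0, 1.0, 2.0], k=3)


def test_unify_thresholds_is_componentwise_median():
    pairs = [(1.0, 10.0), (1.2, 12.0), (0.9, 14.0)]
    assert unify_thresholds(pairs) == (1.0, 12.0)
    with pytest.raises(InvalidInputError):
        unify_thresholds([])


def test_reference_table_medians_reproduce_published_unified_thresholds():
    """Median of the twelve normal-tissue per-sample thresholds rounds to the
    published unified pair (1.06, 12.72)."""
    pairs = list(zip(NORMAL_TISSUE_TRILEVEL["low_threshold"],
                     NORMAL_TISSUE_TRILEVEL["high_threshold"]))
    low, high = unify_thresholds(pairs)
    assert low == pytest.approx(1.055)
    assert round_half_up(low, 2) == UNIFIED_LOW_RPKM == 1.06
    assert round_half_up(high, 2) == UNIFIED_HIGH_RPKM == 12.72


def test_reference_table_rows_internally_consistent():
    t = NORMAL_TISSUE_TRILEVEL
    sums = t["low_count"] + t["moderate_count"] + t["high_count"]
    # The published Kidney row is internally inconsistent as printed
    # (2,868 + 8,991 + 1,710 = 13,569 against a printed total of 13,695);
    # every other row sums exactly.
    consistent = t.index != "Kidney"
    assert (sums[consistent] == t.loc[consistent, "total"]).all()
    assert sums.loc["Testis"] == 15_967
    assert sums.loc["Muscle"] == 11_713
    assert sums.loc["Kidney"] == 13_569 != t.loc["Kidney", "total"]
    assert (t["low_threshold"] < t["high_threshold"]).all()


def test_trilevel_sample_partitions_expressed_genes():
    rng = np.random.default_rng(7)
    vals = np.concatenate([
        np.zeros(50),
        rng.lognormal(np.log(0.5), 0.25, 100),
        rng.lognormal(np.log(6.0), 0.35, 250),
        rng.lognormal(np.log(60.0), 0.30, 60),
    ])
    rec = trilevel_sample(vals, background=0.14, seed=0, max_restarts=5)
    assert rec["low_count"] + rec["moderate_count"] + rec["high_count"] == rec["total"]
    assert rec["total"] == int((vals > 0.14).sum())
    assert rec["low_threshold"] < rec["high_threshold"]


def test_trilevel_table_unifies_over_normal_group(small_study):
    cfg, matrix, truth, intergenic = small_study
    table, (low, high) = trilevel_table(matrix, 0.14, seed=0, max_restarts=5)
    assert list(table.index) == matrix.sample_ids
    normal_ids = matrix.group_columns("normal")
    assert low == pytest.approx(float(np.median(table.loc[normal_ids, "low_threshold"])))
    assert high == pytest.approx(float(np.median(table.loc[normal_ids, "high_threshold"])))
    # planted mode geometry: thresholds fall between adjacent mode supports
    assert 0.9 * np.exp(np.log(0.5)) < low < 1.5 * np.exp(np.log(6.0))
    assert low < high
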