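import numpy as np
import pytest

import strucnet as sn
from oracles import (
    oracle_betweenness,
    oracle_clustering,
    oracle_global_efficiency,
    oracle_local_efficiency,
    oracle_nodal_efficiency,
    oracle_strength,
    oracle_vulnerability,
    random_weighted_graph,
)

TOL = 1e-10


class TestClosedForms:
    def test_triangle(self, triangle):
        np.testing.assert_allclose(sn.nodal_strength(triangle), 2.0)
        np.testing.assert_allclose(sn.local_clustering(triangle), 1.0)
        assert sn.global_efficiency(triangle) == pytest.approx(1.0)
        assert sn.characteristic_path_length(triangle) == pytest.approx(1.0)
        assert sn.clustering_coefficient(triangle) == pytest.approx(1.0)

    def test_star_efficiencies(self, star4):
        e = sn.nodal_efficiency(star4)
        assert e[0] == pytest.approx(1.0)
        np.testing.assert_allclose(e[1:], 2.0 / 3.0)
        assert sn.global_efficiency(star4) == pytest.approx(0.75)
        assert sn.characteristic_path_length(star4) == pytest.approx(4.0 / 3.0)

    def test_star_center_vulnerability_is_one(self, star4):
        v = sn.vulnerability(star4)
        assert v[0] == pytest.approx(1.0)

    def test_star_local_efficiency_zero(self, star4):
        assert sn.local_efficiency(star4) == 0.0

    def test_path3_betweenness(self, path3):
        np.testing.assert_allclose(sn.betweenness(path3), [0.0, 1.0, 0.0])

    def test_path3_clustering_zero(self, path3):
        np.testing.assert_allclose(sn.local_clustering(path3), 0.0)

    def test_complete_graph_betweenness_zero(self):
        w = np.ones((5, 5)) - np.eye(5)
        np.testing.assert_allclose(sn.betweenness(w), 0.0)

    def test_complete_k3_local_efficiency(self, triangle):
        assert sn.local_efficiency(triangle) == pytest.approx(1.0)


class TestEdgeLengths:
    @pytest.mark.parametrize("w,expected", [(1.0, 1.0), (4.0, 0.25)])
    def test_reciprocal(self, w, expected):
        m = np.array([[0, w], [w, 0]], float)
        assert sn.edge_lengths(m)[0, 1] == expected

    def test_absent_edge_infinite(self):
        m = np.zeros((2, 2))
        assert np.isinf(sn.edge_lengths(m)[0, 1])


class TestDegenerateInputs:
    def test_empty_graph(self):
        w = np.zeros((4, 4))
        assert sn.global_efficiency(w) == 0.0
        assert np.isinf(sn.characteristic_path_length(w))
        np.testing.assert_array_equal(sn.nodal_efficiency(w), 0.0)

    def test_vulnerability_undefined_on_empty_graph(self):
        with pytest.raises(ValueError, match="undefined"):
            sn.vulnerability(np.zeros((4, 4)))

    def test_isolated_node_strength_zero(self, star4):
        w = star4.copy()
        w[0, 3] = w[3, 0] = 0.0
        assert sn.nodal_strength(w)[3] == 0.0


class TestOracleEquivalence:
    """Every metric must match an exhaustive brute-force computation."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_metrics_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        w = random_weighted_graph(rng, n)
        np.testing.assert_allclose(sn.nodal_strength(w), oracle_strength(w),
                                   atol=TOL)
        np.testing.assert_allclose(sn.nodal_efficiency(w),
                                   oracle_nodal_efficiency(w), atol=TOL)
        np.testing.assert_allclose(sn.local_clustering(w),
                                   oracle_clustering(w), atol=TOL)
        np.testing.assert_allclose(sn.betweenness(w), oracle_betweenness(w),
                                   atol=TOL)
        assert sn.global_efficiency(w) == pytest.approx(
            oracle_global_efficiency(w), abs=TOL)
        assert sn.local_efficiency(w) == pytest.approx(
            oracle_local_efficiency(w), abs=TOL)
        if sn.global_efficiency(w) > 0:
            np.testing.assert_allclose(sn.vulnerability(w),
                                       oracle_vulnerability(w), atol=TOL)


class TestInvariants:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_global_efficiency_is_mean_nodal(self, seed):
        w = random_weighted_graph(np.random.default_rng(seed), 10)
        assert sn.global_efficiency(w) == pytest.approx(
            sn.nodal_efficiency(w).mean(), abs=1e-14)

    @pytest.mark.parametrize("seed", [3, 11])
    def test_path_length_identity(self, seed):
        w = random_weighted_graph(np.random.default_rng(seed), 10, density=0.7)
        assert sn.characteristic_path_length(w) * sn.global_efficiency(w) == (
            pytest.approx(1.0, abs=1e-14))

    def test_clustering_coefficient_is_mean_local(self):
        w = random_weighted_graph(np.random.default_rng(5), 12)
        assert sn.clustering_coefficient(w) == pytest.approx(
            sn.local_clustering(w).mean(), abs=1e-14)

    @pytest.mark.parametrize("seed", [0, 4])
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, 9)
        perm = rng.permutation(9)
        wp = w[np.ix_(perm, perm)]
        for metric in (sn.nodal_strength, sn.nodal_efficiency,
                       sn.local_clustering, sn.betweenness):
            np.testing.assert_allclose(metric(w)[perm], metric(wp), atol=1e-12)
        assert sn.global_efficiency(wp) == pytest.approx(
            sn.global_efficiency(w), abs=1e-12)

    def test_bounds(self):
        w = random_weighted_graph(np.random.default_rng(2), 12, density=0.5)
        assert (sn.local_clustering(w) <= 1 + 1e-12).all()
        b = sn.betweenness(w)
        assert ((b >= 0) & (b <= 1)).all()
        if sn.global_efficiency(w) > 0:
            assert (sn.vulnerability(w) <= 1 + 1e-12).all()


class TestGraphMetricsTransformer:
    def test_tidy_output_consistent_with_functions(self, small_cohort):
        connectomes, _, _ = small_cohort
        sub = connectomes[:2]
        tidy = sn.GraphMetrics().transform(sub)
        assert set(tidy.columns) == {"subject_id", "node", "metric", "value"}
        c = sub[0]
        mine = tidy[tidy.subject_id == c.subject_id]
        s = mine[(mine.metric == "strength")].set_index("node")["value"]
        np.testing.assert_allclose(
            s.loc[c.labels].to_numpy(), sn.nodal_strength(c.weights))
        g = mine[mine.node == "GLOBAL"].set_index("metric")["value"]
        assert g["global_efficiency"] == pytest.approx(
            sn.global_efficiency(c.weights))
        assert g["characteristic_path_length"] * g["global_efficiency"] == (
            pytest.approx(1.0))
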