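import numpy as np
import pytest

import strucnet as sn


class TestSimulateCohort:
    def test_fixed_seed_reproduces_cohort(self):
        cfg = sn.SimulationConfig(seed=3, n_controls=3, n_patients=2)
        a, da, _ = sn.simulate_cohort(cfg)
        b, db, _ = sn.simulate_cohort(cfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.weights, cb.weights)
        assert da.to_frame().equals(db.to_frame())

    def test_outputs_are_valid_connectomes(self, small_cohort):
        connectomes, design, _ = small_cohort
        assert len(connectomes) == design.n_subjects
        for c in connectomes:
            assert sn.validate_connectome(c) == []

    def test_shared_backbone_topology(self, small_cohort):
        connectomes, _, _ = small_cohort
        topo = connectomes[0].weights > 0
        for c in connectomes[1:]:
            np.testing.assert_array_equal(c.weights > 0, topo)

    def test_null_factor_identical_to_no_effect(self):
        base = sn.SimulationConfig(seed=9, n_controls=3, n_patients=3)
        _, _, truth = sn.simulate_cohort(base)
        edges = sn.select_connected_edges(truth.backbone_weights, 4,
                                          np.random.default_rng(0))
        null = sn.SimulationConfig(seed=9, n_controls=3, n_patients=3,
                                   effects=[sn.EffectSpec(edges, factor=1.0)])
        a, _, _ = sn.simulate_cohort(base)
        b, _, _ = sn.simulate_cohort(null)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.weights, cb.weights)

    def test_attenuation_shows_in_group_means(self):
        probe = sn.SimulationConfig(seed=13, n_controls=20, n_patients=20)
        _, _, truth = sn.simulate_cohort(probe)
        edges = sn.select_connected_edges(truth.backbone_weights, 8,
                                          np.random.default_rng(1))
        cfg = sn.SimulationConfig(seed=13, n_controls=20, n_patients=20,
                                  effects=[sn.EffectSpec(edges, factor=0.7)])
        cs, design, truth = sn.simulate_cohort(cfg)
        e = np.array(truth.effect_edges)
        w = np.stack([c.weights for c in cs])
        pat = w[design.group == 1][:, e[:, 0], e[:, 1]].mean()
        ctrl = w[design.group == 0][:, e[:, 0], e[:, 1]].mean()
        assert pat / ctrl == pytest.approx(0.7, abs=0.07)

    def test_effect_edge_absent_from_backbone_raises(self):
        probe = sn.SimulationConfig(seed=1, n_controls=2, n_patients=2)
        _, _, truth = sn.simulate_cohort(probe)
        absent = tuple(np.argwhere(np.triu(truth.backbone_weights == 0, 1))[0])
        cfg = sn.SimulationConfig(
            seed=1, n_controls=2, n_patients=2,
            effects=[sn.EffectSpec([(int(absent[0]), int(absent[1]))], 0.7)])
        with pytest.raises(ValueError, match="backbone"):
            sn.simulate_cohort(cfg)

    def test_effect_spec_direction(self):
        assert sn.EffectSpec([(0, 1)], 0.7).direction == "decrease"
        assert sn.EffectSpec([(0, 1)], 1.3).direction == "increase"
        with pytest.raises(ValueError):
            sn.EffectSpec([(0, 1)], 0.0)

    def test_design_covariates_plausible(self, small_cohort):
        _, design, _ = small_cohort
        assert set(np.unique(design.sex)) <= {0.0, 1.0}
        assert design.age.min() >= 18
        assert design.age.max() <= 65


class TestSelectConnectedEdges:
    @pytest.mark.parametrize("n_edges", [3, 8, 15])
    def test_selected_set_is_connected(self, n_edges, small_cohort):
        _, _, truth = small_cohort
        import networkx as nx

        edges = sn.select_connected_edges(truth.backbone_weights, n_edges,
                                          np.random.default_rng(5))
        assert len(edges) == n_edges
        g = nx.Graph(edges)
        assert nx.is_connected(g)
        for i, j in edges:
            assert truth.backbone_weights[i, j] > 0


class TestStreamlineSummaryRoundTrip:
    def test_reconstruction_within_count_rounding(self, small_cohort, atlas):
        connectomes, _, _ = small_cohort
        c = connectomes[0]
        s = sn.simulate_streamline_summary(c, rng=2)
        rebuilt = sn.build_connectome(s, atlas)
        orig = c.weights
        # edges whose implied count reached the threshold must round-trip
        kept = s.counts >= 3
        rel = np.abs(rebuilt.weights[kept] - orig[kept]) / orig[kept]
        assert rel.max() <= 0.5 / 3 + 1e-9  # half-count rounding bound
        # below-threshold pairs are reconstructed as zero by design
        assert not rebuilt.weights[(s.counts > 0) & ~kept].any()

    def test_zero_weight_edges_have_zero_count(self, small_cohort):
        connectomes, _, _ = small_cohort
        c = connectomes[0]
        s = sn.simulate_streamline_summary(c, rng=0)
        assert not s.counts[c.weights == 0].any()

    def test_counts_are_plausible_streamline_numbers(self, small_cohort):
        connectomes, _, _ = small_cohort
        s = sn.simulate_streamline_summary(connectomes[0], rng=1)
        per_edge = s.counts[np.triu_indices_from(s.counts, 1)]
        per_edge = per_edge[per_edge > 0]
        assert 5 < np.median(per_edge) < 200
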