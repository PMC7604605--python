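import numpy as np
import pytest

import strucnet as sn
from strucnet.atlas import CohortDesign


@pytest.fixture
def design():
    rng = np.random.default_rng(11)
    n0, n1 = 14, 12
    return CohortDesign(
        subject_ids=[f"s{i}" for i in range(n0 + n1)],
        group=np.r_[np.zeros(n0), np.ones(n1)],
        age=rng.normal(26, 5, n0 + n1).round(1),
        sex=rng.integers(0, 2, n0 + n1),
    )


class TestPermutationGLM:
    def test_constant_response_is_degenerate(self, design):
        with pytest.raises(ValueError, match="degenerate"):
            sn.permutation_glm(np.ones(design.n_subjects), design, n_perm=50)

    def test_too_few_subjects_per_group(self):
        d = CohortDesign(["a", "b", "c"], [0, 0, 1], [20, 21, 22], [0, 1, 0])
        with pytest.raises(ValueError, match="2 subjects"):
            sn.permutation_glm([1.0, 2.0, 3.0], d, n_perm=50)

    def test_p_values_never_zero_and_bounded(self, design):
        rng = np.random.default_rng(0)
        y = rng.normal(size=design.n_subjects)
        y[design.group == 1] += 10.0  # overwhelming effect
        res = sn.permutation_glm(y, design, n_perm=200, tail="greater", seed=0)
        assert res.p_uncorrected == pytest.approx(1.0 / 201.0)

    def test_seeded_reproducibility(self, design):
        y = np.random.default_rng(1).normal(size=design.n_subjects)
        a = sn.permutation_glm(y, design, n_perm=300, tail="greater", seed=5)
        b = sn.permutation_glm(y, design, n_perm=300, tail="greater", seed=5)
        assert (a.observed_stat, a.p_uncorrected) == (b.observed_stat, b.p_uncorrected)

    def test_flipping_group_labels_negates_statistic(self, design):
        y = np.random.default_rng(2).normal(size=design.n_subjects)
        flipped = CohortDesign(design.subject_ids, 1 - design.group,
                               design.age, design.sex)
        a = sn.permutation_glm(y, design, n_perm=50, tail="greater", seed=0)
        b = sn.permutation_glm(y, flipped, n_perm=50, tail="greater", seed=0)
        assert a.observed_stat == pytest.approx(-b.observed_stat, rel=1e-10)

    def test_both_tails_returned_by_default(self, design):
        y = np.random.default_rng(3).normal(size=design.n_subjects)
        res = sn.permutation_glm(y, design, n_perm=100, seed=0)
        assert set(res) == {"greater", "less"}
        # shared stream: the two tails cannot both be small under the null
        assert res["greater"].p_uncorrected + res["less"].p_uncorrected > 1.0

    def test_large_planted_shift_detected(self, design):
        detected = 0
        rng = np.random.default_rng(4)
        for rep in range(10):
            y = rng.normal(size=design.n_subjects)
            y[design.group == 1] += 3.0
            r = sn.permutation_glm(y, design, n_perm=300, tail="greater", seed=rep)
            detected += r.p_uncorrected < 0.05
        assert detected >= 9

    def test_estimator_wrapper(self, design):
        y = np.random.default_rng(5).normal(size=design.n_subjects)
        est = sn.PermutationGLM(n_perm=100, tail="greater", random_state=1)
        est.fit(y, design)
        ref = sn.permutation_glm(y, design, n_perm=100, tail="greater", seed=1)
        assert est.results_.p_uncorrected == ref.p_uncorrected
        assert est.get_params()["n_perm"] == 100


class TestNodalComparison:
    def test_single_node_fwe_equals_uncorrected(self, design):
        y = np.random.default_rng(6).normal(size=(design.n_subjects, 1))
        df = sn.nodal_comparison(y, design, n_perm=300, tail="greater", seed=0)
        assert df["p_fwe"].iloc[0] == pytest.approx(df["p_uncorrected"].iloc[0])

    def test_fwe_never_smaller_than_uncorrected(self, design):
        y = np.random.default_rng(7).normal(size=(design.n_subjects, 20))
        df = sn.nodal_comparison(y, design, n_perm=300, seed=0)
        assert (df["p_fwe"] >= df["p_uncorrected"] - 1e-12).all()

    def test_fwe_rejections_subset_of_uncorrected(self, design):
        y = np.random.default_rng(8).normal(size=(design.n_subjects, 30))
        y[design.group == 1, 4] += 2.0
        df = sn.nodal_comparison(y, design, n_perm=500, tail="greater", seed=0)
        fwe = set(df[df["p_fwe"] < 0.05]["node"])
        unc = set(df[df["p_uncorrected"] < 0.05]["node"])
        assert fwe <= unc

    def test_planted_node_attains_smallest_fwe(self, design):
        hits = 0
        rng = np.random.default_rng(9)
        for rep in range(10):
            y = rng.normal(size=(design.n_subjects, 40))
            y[design.group == 1, 13] += 3.0
            df = sn.nodal_comparison(y, design, n_perm=300, tail="greater",
                                     seed=rep)
            hits += df.loc[df["p_fwe"].idxmin(), "node"] == "13"
        assert hits >= 9

    def test_constant_node_is_degenerate(self, design):
        y = np.random.default_rng(10).normal(size=(design.n_subjects, 3))
        y[:, 1] = 7.0
        with pytest.raises(ValueError, match="degenerate"):
            sn.nodal_comparison(y, design, n_perm=50)

    def test_dataframe_columns_become_node_labels(self, design):
        import pandas as pd

        y = pd.DataFrame(
            np.random.default_rng(11).normal(size=(design.n_subjects, 2)),
            columns=["STG.L", "STG.R"],
        )
        df = sn.nodal_comparison(y, design, n_perm=100, tail="less", seed=0)
        assert set(df["node"]) == {"STG.L", "STG.R"}
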