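import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import subnetmarkers as sm
from oracles import welch_t
from subnetmarkers.datasets import ValidationError


def _dataset(values, labels, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return sm.ExpressionDataset(
        genes, [f"s{j}" for j in range(values.shape[1])], values, np.asarray(labels)
    )


class TestEstimateParams:
    def test_two_point_mean_sd(self):
        ds = _dataset([[0.0, 2.0, 9.0, 9.0]], [1, 1, 2, 2])
        p = sm.estimate_params(ds)
        assert p.mu[0, 0] == pytest.approx(1.0)
        assert p.sigma[0, 0] == pytest.approx(math.sqrt(2.0))

    def test_constant_class_floored(self):
        ds = _dataset([[5.0, 5.0, 5.0, 1.0, 2.0]], [1, 1, 1, 2, 2])
        p = sm.estimate_params(ds)
        assert p.sigma[0, 0] == p.sigma_floor > 0

    def test_identical_classes_symmetric(self):
        ds = _dataset([[1.0, 4.0, 1.0, 4.0]], [1, 1, 2, 2])
        p = sm.estimate_params(ds)
        assert p.mu[0, 0] == p.mu[1, 0]
        assert p.sigma[0, 0] == p.sigma[1, 0]


class TestComputeLLR:
    def test_identical_densities_give_zero(self):
        ds = _dataset([[1.0, 4.0, 1.0, 4.0]], [1, 1, 2, 2])
        llr = sm.compute_llr(ds, sm.estimate_params(ds))
        assert np.allclose(llr.to_numpy(), 0.0)

    def test_symmetric_point_and_unit_step(self):
        # mu1=1, mu2=-1, sigma=1: alpha(0) = 0, alpha(1) = 2
        params = sm.GaussianParams(["g"], np.array([[1.0], [-1.0]]),
                                   np.array([[1.0], [1.0]]), 1e-9)
        ds = _dataset([[0.0, 1.0, 0.0, 1.0]], [1, 1, 2, 2], genes=["g"])
        llr = sm.compute_llr(ds, params)
        assert llr.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert llr.iloc[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_gaussian_logdensity_difference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        mu = rng.normal(size=(2, 1))
        sigma = rng.uniform(0.5, 2.0, size=(2, 1))
        params = sm.GaussianParams(["g"], mu, sigma, 1e-9)
        ds = _dataset(x[None, :], [1] * 100 + [2] * 100, genes=["g"])
        expected = stats.norm.logpdf(x, mu[0], sigma[0]) - stats.norm.logpdf(x, mu[1], sigma[1])
        assert np.allclose(sm.compute_llr(ds, params).to_numpy()[0], expected, atol=1e-10)

    def test_shift_invariance_of_t_alpha(self):
        # adding a constant to a gene's expression shifts both class means
        # equally, leaving its LLR t-score unchanged
        rng = np.random.default_rng(1)
        values = rng.normal(size=(3, 40)) + np.array([[0.5], [0.0], [1.0]]) * np.repeat([1, -1], 20)
        labels = [1] * 20 + [2] * 20
        ds1 = _dataset(values, labels)
        ds2 = _dataset(values + np.array([[10.0], [0.0], [-3.0]]), labels)
        t1 = sm.gene_t_scores(sm.compute_llr(ds1, sm.estimate_params(ds1)), ds1.labels)
        t2 = sm.gene_t_scores(sm.compute_llr(ds2, sm.estimate_params(ds2)), ds2.labels)
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), atol=1e-9)


class TestSubnetworkActivity:
    llr = pd.DataFrame([[1.0, 2.0], [0.0, 1.0], [3.0, 0.0]],
                       index=["a", "b", "c"], columns=["s1", "s2"])

    def test_single_gene_is_its_row(self):
        assert np.allclose(sm.subnetwork_activity(["b"], self.llr), [0.0, 1.0])

    def test_opposite_rows_cancel(self):
        llr = pd.DataFrame([[1.0, -2.0], [-1.0, 2.0]], index=["a", "b"])
        assert np.allclose(sm.subnetwork_activity(["a", "b"], llr), 0.0)

    def test_sum_arithmetic(self):
        assert np.allclose(sm.subnetwork_activity(["a", "b", "c"], self.llr), [4.0, 3.0])

    def test_additive_over_disjoint_sets(self):
        both = sm.subnetwork_activity(["a", "b", "c"], self.llr)
        split = sm.subnetwork_activity(["a"], self.llr) + sm.subnetwork_activity(["b", "c"], self.llr)
        assert np.allclose(both, split)

    def test_unknown_member_raises(self):
        with pytest.raises(KeyError):
            sm.subnetwork_activity(["zz"], self.llr)
        with pytest.raises(ValidationError):
            sm.subnetwork_activity([], self.llr)


class TestTStatistic:
    def test_null_case_zero(self):
        assert sm.t_statistic([1.0, 2.0, 1.0, 2.0], [1, 1, 2, 2]) == pytest.approx(0.0)

    def test_label_swap_negates(self):
        values = [1.0, 3.0, 2.0, 7.0, 5.0, 6.0]
        labels = np.array([1, 1, 1, 2, 2, 2])
        t12 = sm.t_statistic(values, labels)
        t21 = sm.t_statistic(values, 3 - labels)
        assert t12 == pytest.approx(-t21)

    def test_matches_textbook_welch_and_scipy(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array([1, 1, 1, 2, 2, 2])
        t = sm.t_statistic(values, labels)
        assert t == pytest.approx(welch_t(values[:3], values[3:]))
        assert t == pytest.approx(
            stats.ttest_ind(values[:3], values[3:], equal_var=False).statistic
        )

    def test_student_flavor_matches_scipy(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=12)
        labels = np.array([1] * 5 + [2] * 7)
        t = sm.t_statistic(values, labels, kind="student")
        assert t == pytest.approx(
            stats.ttest_ind(values[:5], values[5:], equal_var=True).statistic
        )

    def test_degenerate_spread_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert sm.t_statistic([5.0, 5.0, 5.0, 5.0], [1, 1, 2, 2]) == 0.0
        assert any("degenerate" in rec.message for rec in caplog.records)


class TestGeneTScores:
    def test_zero_llr_row_scores_zero(self):
        llr = pd.DataFrame(np.zeros((1, 6)), index=["g"])
        assert sm.gene_t_scores(llr, [1, 1, 1, 2, 2, 2])["g"] == 0.0

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(3)
        row = rng.normal(size=20)
        llr = pd.DataFrame([row, 7.0 * row], index=["g", "g7"])
        t = sm.gene_t_scores(llr, [1] * 10 + [2] * 10)
        assert t["g"] == pytest.approx(t["g7"])

    def test_matches_per_row_t_statistic(self):
        rng = np.random.default_rng(4)
        llr = pd.DataFrame(rng.normal(size=(5, 30)))
        labels = np.array([1] * 14 + [2] * 16)
        t = sm.gene_t_scores(llr, labels)
        for i in range(5):
            assert t.iloc[i] == pytest.approx(sm.t_statistic(llr.iloc[i], labels))

    def test_planted_signal_positive(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(2, 1, 50), rng.normal(-2, 1, 50)])
        ds = _dataset(values[None, :], [1] * 50 + [2] * 50)
        t = sm.gene_t_scores(sm.compute_llr(ds, sm.estimate_params(ds)), ds.labels)
        assert t.iloc[0] > 3.0


def test_llr_t_grows_with_class_separation():
    """|t| of a gene's LLR increases with the class-mean separation."""
    scores = []
    for delta in (0.5, 1.5, 3.0):
        rng = np.random.default_rng(17)
        noise = rng.normal(size=100)
        values = noise + delta / 2.0 * np.repeat([1.0, -1.0], 50)
        ds = _dataset(values[None, :], [1] * 50 + [2] * 50)
        t = sm.gene_t_scores(sm.compute_llr(ds, sm.estimate_params(ds)), ds.labels)
        scores.append(abs(t.iloc[0]))
    assert scores[0] < scores[1] < scores[2]
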