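import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import subnetmarkers as sm
from oracles import pair_count_auc
from subnetmarkers.datasets import ValidationError


class TestAUC:
    def test_perfect_ordering(self):
        assert sm.auc([5, 4, 1, 0], [1, 1, 2, 2]) == 1.0

    def test_anti_ordering(self):
        assert sm.auc([0, 1, 4, 5], [1, 1, 2, 2]) == 0.0

    def test_frozen_pair_count_example(self):
        scores, labels = [1, 2, 3, 4], [2, 1, 2, 1]
        expected = pair_count_auc(scores, labels)  # = 0.75 by hand
        assert expected == 0.75
        assert sm.auc(scores, labels) == pytest.approx(expected)

    def test_ties_contribute_half(self):
        assert sm.auc([1, 1, 1, 1], [1, 1, 2, 2]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            sm.auc([1, 2], [1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_matches_pair_count_and_sklearn(self, data):
        n = data.draw(st.integers(min_value=4, max_value=12))
        scores = data.draw(st.lists(st.integers(min_value=-5, max_value=5),
                                    min_size=n, max_size=n))
        labels = data.draw(st.lists(st.sampled_from([1, 2]), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 1, 2
        got = sm.auc(scores, labels)
        assert got == pytest.approx(pair_count_auc(scores, labels))
        assert got == pytest.approx(
            roc_auc_score([1 if l == 1 else 0 for l in labels], scores)
        )

    def test_complement_under_negation(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)  # continuous, tie-free
        labels = rng.choice([1, 2], size=30)
        labels[:2] = [1, 2]
        assert sm.auc(scores, labels) + sm.auc(-scores, labels) == pytest.approx(1.0)


class TestErrorAtTPR:
    def test_perfect_separation_zero_error(self):
        curve = sm.error_at_tpr([4, 3, 1, 0], [1, 1, 2, 2], [0.5, 1.0])
        assert np.allclose(curve[:, 1], 0.0)

    def test_hand_enumerated_overlap(self):
        # positives score (5, 1), negatives (4, 3, 2, 0); TPR=1 forces the
        # threshold down to 1, misclassifying negatives 4, 3, 2
        curve = sm.error_at_tpr([5, 1, 4, 3, 2, 0], [1, 1, 2, 2, 2, 2], [0.5, 1.0])
        assert curve[0, 1] == pytest.approx(1 / 6)  # threshold 5: one missed positive
        assert curve[1, 1] == pytest.approx(3 / 6)

    def test_random_scores_mid_tpr_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = np.array([1] * 1000 + [2] * 1000)
        curve = sm.error_at_tpr(scores, labels, [0.5])
        assert abs(curve[0, 1] - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            sm.error_at_tpr([1, 2], [1, 1], [0.5])


class TestMeanTopK:
    def _llr(self):
        # three "markers" over singleton genes with distinct signals
        rng = np.random.default_rng(2)
        labels = np.array([1] * 20 + [2] * 20)
        c = np.where(labels == 1, 1.0, -1.0)
        rows = [3.0 * c, 2.0 * c + rng.normal(0, 1, 40), rng.normal(0, 1, 40)]
        return pd.DataFrame(rows, index=["a", "b", "c"]), labels

    def test_mean_of_top_k(self):
        llr, labels = self._llr()
        defs = [("ma", ["a"]), ("mb", ["b"]), ("mc", ["c"])]
        t = sm.marker_activity_tscores(defs, llr, labels)
        out = sm.mean_topk_tscore(defs, llr, labels, K_values=[1, 2])
        top = sorted(t, reverse=True)
        assert out[1] == pytest.approx(top[0])
        assert out[2] == pytest.approx(np.mean(top[:2]))

    def test_k_clipped_to_marker_count(self):
        llr, labels = self._llr()
        defs = [("ma", ["a"])]
        out = sm.mean_topk_tscore(defs, llr, labels, K_values=[10])
        assert out[10] == pytest.approx(
            sm.marker_activity_tscores(defs, llr, labels)["ma"]
        )


class TestBaselines:
    def _llr(self):
        rng = np.random.default_rng(3)
        labels = np.array([1] * 30 + [2] * 30)
        c = np.where(labels == 1, 1.0, -1.0)
        rows = {g: w * c + rng.normal(0, 1, 60)
                for g, w in [("a", 2.0), ("b", 1.5), ("c", 1.0), ("d", 0.0)]}
        return pd.DataFrame(rows).T, labels

    def test_gene_baseline_sort_and_cut(self):
        llr, labels = self._llr()
        defs = [("m1", ["a", "b"]), ("m2", ["c", "d"])]
        top2 = sm.gene_marker_baseline(defs, llr, labels, top_n=2)
        assert [name for name, _ in top2] == ["a", "b"]
        assert all(genes == [name] for name, genes in top2)

    def test_gene_baseline_pool_smaller_than_top_n(self):
        llr, labels = self._llr()
        out = sm.gene_marker_baseline([("m", ["a", "b"])], llr, labels, top_n=50)
        assert len(out) == 2

    def test_gene_baseline_order_invariant(self):
        llr, labels = self._llr()
        defs = [("m1", ["a", "b"]), ("m2", ["c", "d"])]
        assert sm.gene_marker_baseline(defs, llr, labels) == \
            sm.gene_marker_baseline(defs[::-1], llr, labels)

    def test_average_t_ranking_mean_and_ties(self):
        llr = pd.DataFrame([[1.0, 2.0, -1.0, -2.0]] * 3, index=["a", "b", "c"])
        labels = [1, 1, 2, 2]
        t = sm.gene_t_scores(llr, labels).abs()
        ranked = sm.average_t_ranking(
            [("set2", ["a", "b"]), ("set1", ["c"]), ("set3", ["b", "c"])], llr, labels
        )
        # all genes identical -> equal scores, ties broken by name
        assert [name for name, _ in ranked] == ["set1", "set2", "set3"]
        assert ranked[0][1] == pytest.approx(t["c"])

    def test_average_t_ranking_skips_missing_members(self, caplog):
        llr, labels = self._llr()
        with caplog.at_level("WARNING"):
            ranked = sm.average_t_ranking([("s", ["a", "zz"])], llr, labels)
        t = sm.gene_t_scores(llr, labels).abs()
        assert ranked[0][1] == pytest.approx(t["a"])
        assert any("absent" in rec.message for rec in caplog.records)

    def test_mean_expression_activity(self, tiny_dataset):
        one = sm.mean_expression_activity(["ga"], tiny_dataset)
        df = tiny_dataset.to_frame()
        z = (df.loc["ga"] - df.loc["ga"].mean()) / df.loc["ga"].std(ddof=1)
        assert np.allclose(one, z.to_numpy())
        # two genes that are exact negatives after normalisation cancel
        ds = sm.ExpressionDataset(
            ["u", "v"], ["s1", "s2", "s3", "s4"],
            np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]]),
            np.array([1, 1, 2, 2]),
        )
        assert np.allclose(sm.mean_expression_activity(["u", "v"], ds), 0.0)


@pytest.fixture(scope="module")
def cv_case():
    net, truth, ds = sm.planted_fixture(n_nodes=80, n_modules=2, module_size=5,
                                        n1=40, n2=40, seed=11, p=0.04)
    defs = [(f"mod{i}", module) for i, module in enumerate(truth.modules)]
    return ds, defs


class TestNestedCV:
    def test_separable_markers_reach_high_auc(self, cv_case):
        ds, defs = cv_case
        res = sm.nested_cv(ds, defs, n_repeats=2, seed=5)
        assert res.mean_auc > 0.95

    def test_no_test_fold_leakage(self, cv_case):
        """Sample indices used for estimation, ranking or selection never
        intersect the held-out test fold."""
        ds, defs = cv_case
        res = sm.nested_cv(ds, defs, n_repeats=2, seed=6)
        for rec in res.fold_records:
            test = set(rec["test_idx"].tolist())
            assert not test & set(rec["estimation_idx"].tolist())
            assert not test & set(rec["ranking_idx"].tolist())
            assert not test & set(rec["selection_idx"].tolist())
            assert set(rec["ranking_idx"].tolist()).isdisjoint(rec["selection_idx"].tolist())

    def test_forward_selection_never_below_top1(self, cv_case):
        ds, defs = cv_case
        res = sm.nested_cv(ds, defs, n_repeats=2, seed=7)
        for rec in res.fold_records:
            assert rec["selection_auc_final"] >= rec["selection_auc_top1"]

    def test_folds_stratified_within_one_sample(self, cv_case):
        ds, defs = cv_case
        res = sm.nested_cv(ds, defs, n_repeats=1, seed=8)
        global_frac = np.mean(ds.labels == 1)
        for rec in res.fold_records:
            test = rec["test_idx"]
            n1 = int(np.sum(ds.labels[test] == 1))
            assert abs(n1 - global_frac * len(test)) <= 1.0

    def test_single_marker_pool_completes(self, cv_case):
        ds, defs = cv_case
        res = sm.nested_cv(ds, defs[:1], n_repeats=1, seed=9)
        assert all(rec["selected"] == [defs[0][0]] for rec in res.fold_records)
        assert 0.0 <= res.mean_auc <= 1.0

    def test_mean_expression_scheme_differs(self, cv_case):
        ds, defs = cv_case
        a = sm.nested_cv(ds, defs, activity_scheme="llr_sum", n_repeats=1, seed=10)
        b = sm.nested_cv(ds, defs, activity_scheme="mean_expression", n_repeats=1, seed=10)
        assert not np.allclose(a.pooled_scores, b.pooled_scores)
        assert b.mean_auc > 0.9  # planted signal is strong either way

    def test_unknown_marker_genes_warn_and_drop(self, cv_case, caplog):
        ds, defs = cv_case
        noisy = defs + [("ghost", ["nope1", "nope2"])]
        with caplog.at_level("WARNING"):
            res = sm.nested_cv(ds, noisy, n_repeats=1, seed=11)
        assert any("dropped" in rec.message for rec in caplog.records)
        assert res.mean_auc > 0.9
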