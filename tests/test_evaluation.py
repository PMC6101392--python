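"""Metrics, stratified folds, cross-validation, and grid search."""

import itertools

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from conftest import make_matrix
from genesel.evaluation import (
    ConfusionCounts,
    accuracy,
    auc,
    confusion,
    cross_validate,
    grid_search,
    mcc,
    stratified_kfold,
)
from genesel.pipelines import LlsvmPipeline


class TestConfusion:
    def test_hand_count(self):
        t = list("+++++-----")
        p = list("+++-------")
        p[9] = "+"
        c = confusion(t, p, positive_class="+")
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 2, 4, 1)

    def test_perfect_prediction(self):
        c = confusion([1, -1, 1], [1, -1, 1], positive_class=1)
        assert c.fp == c.fn == 0

    def test_swapping_positive_class(self):
        t = [1, 1, -1, -1, -1]
        p = [1, -1, -1, -1, 1]
        a = confusion(t, p, positive_class=1)
        b = confusion(t, p, positive_class=-1)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tn, b.fn, b.tp, b.fp)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1], [1, -1], positive_class=1)


class TestScalarMetrics:
    def test_accuracy_hand(self):
        assert accuracy(ConfusionCounts(3, 1, 4, 2)) == pytest.approx(0.7)

    def test_accuracy_extremes(self):
        assert accuracy(ConfusionCounts(5, 0, 5, 0)) == 1.0
        assert accuracy(ConfusionCounts(0, 5, 0, 5)) == 0.0

    def test_mcc_hand(self):
        # (3*4 - 1*2) / sqrt(4*5*5*6)
        assert mcc(ConfusionCounts(3, 1, 4, 2)) == pytest.approx(10 / np.sqrt(600))

    def test_mcc_perfect_is_one(self):
        assert mcc(ConfusionCounts(tp=4, fp=0, tn=6, fn=0)) == 1.0

    def test_mcc_degenerate_zero(self):
        assert mcc(ConfusionCounts(tp=5, fp=5, tn=0, fn=0)) == 0.0

    def test_mcc_sign_flips_on_inverted_predictions(self):
        rng = np.random.default_rng(0)
        t = rng.choice([-1, 1], 30)
        p = rng.choice([-1, 1], 30)
        a = mcc(confusion(t, p, 1))
        b = mcc(confusion(t, -p, 1))
        assert a == pytest.approx(-b)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.3], [1, 1, -1], positive_class=1) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [1, 1, 1, -1, -1, -1], 1) == 0.5

    def test_pair_counting_hand(self):
        assert auc([0.8, 0.4, 0.6, 0.2], [1, 1, -1, -1], 1) == pytest.approx(0.75)

    def test_matches_brute_force_pairs(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        t = rng.choice([-1, 1], 40)
        pos = s[t == 1]
        neg = s[t == -1]
        brute = np.mean([
            1.0 if a > b else 0.5 if a == b else 0.0
            for a, b in itertools.product(pos, neg)
        ])
        assert auc(s, t, 1) == pytest.approx(brute)

    def test_complement_identity(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=25)  # continuous: ties have measure zero
        t = rng.choice([-1, 1], 25)
        assert auc(s, t, 1) + auc(-s, t, 1) == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1.0, 2.0], [1, 1], 1)


class TestStratifiedKfold:
    def test_divisible_case_exact(self):
        labels = np.repeat([-1, 1], 40)
        plan = stratified_kfold(labels, k=5, seed=0)
        for _, test in plan.folds():
            assert np.sum(labels[test] == -1) == 8
            assert np.sum(labels[test] == 1) == 8

    def test_cns_shaped_proportions(self):
        """21/39 split over 5 folds: per-fold class counts within one
        sample of the exact proportion (exhaustive check)."""
        labels = np.concatenate([np.full(21, -1), np.full(39, 1)])
        plan = stratified_kfold(labels, k=5, seed=3)
        for _, test in plan.folds():
            n_min = np.sum(labels[test] == -1)
            n_maj = np.sum(labels[test] == 1)
            assert abs(n_min - 21 / 5) < 1
            assert abs(n_maj - 39 / 5) < 1

    def test_partition_and_determinism(self):
        labels = np.random.default_rng(4).choice([-1, 1], 47)
        a = stratified_kfold(labels, k=5, seed=9)
        b = stratified_kfold(labels, k=5, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        assert sorted(np.concatenate([t for _, t in a.folds()])) == list(range(47))

    def test_agrees_with_sklearn_on_fold_sizes(self):
        """Independent check: per-fold class counts match sklearn's
        stratified splitter (assignments may differ, proportions must not)."""
        labels = np.concatenate([np.full(21, -1), np.full(39, 1)])
        ours = stratified_kfold(labels, k=5, seed=0)
        ref = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for cls in (-1, 1):
            ours_counts = sorted(
                int(np.sum(labels[t] == cls)) for _, t in ours.folds()
            )
            ref_counts = sorted(
                int(np.sum(labels[t] == cls))
                for _, t in ref.split(np.zeros((60, 1)), labels)
            )
            assert ours_counts == ref_counts

    def test_class_smaller_than_k(self):
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold([1, 1, 1, -1], k=3)


class _ConstantPipeline:
    def fit(self, m):
        return self

    def predict(self, X):
        return np.ones(len(X), dtype=int)

    def decision_scores(self, X):
        return np.zeros(len(X))


class _SpyPipeline(_ConstantPipeline):
    """Records which sample ids each fit call saw (leakage detector)."""

    seen: list = []

    def fit(self, m):
        _SpyPipeline.seen.append(set(m.sample_ids))
        return self


class TestCrossValidate:
    def _balanced(self, n=40, d=6, seed=0):
        rng = np.random.default_rng(seed)
        return make_matrix(rng.normal(size=(n, d)), np.repeat([-1, 1], n // 2))

    def test_constant_pipeline_is_chance(self):
        m = self._balanced()
        plan = stratified_kfold(m.labels, k=5, seed=1)
        mean, _ = cross_validate(m, _ConstantPipeline, plan)
        assert mean.acc == pytest.approx(0.5)
        assert mean.mcc == 0.0

    def test_no_leakage_of_test_rows_into_fit(self):
        m = self._balanced()
        plan = stratified_kfold(m.labels, k=5, seed=2)
        _SpyPipeline.seen = []
        cross_validate(m, _SpyPipeline, plan)
        for (train, test), seen in zip(plan.folds(), _SpyPipeline.seen):
            held_out = {m.sample_ids[i] for i in test}
            assert not held_out & seen

    def test_separable_llsvm_is_perfect(self, separable):
        plan = stratified_kfold(separable.labels, k=5, seed=3)
        mean, folds = cross_validate(separable, lambda: LlsvmPipeline(C=1.0), plan)
        assert mean.acc == 1.0
        assert mean.auc == 1.0
        assert mean.mcc == 1.0
        assert len(folds) == 5

    def test_pipeline_failure_names_fold(self):
        m = self._balanced()
        plan = stratified_kfold(m.labels, k=4, seed=4)

        class Boom(_ConstantPipeline):
            def fit(self, _m):
                raise RuntimeError("nope")

        with pytest.raises(RuntimeError, match="fold 0"):
            cross_validate(m, Boom, plan)


class TestGridSearch:
    def test_single_point(self, separable):
        plan = stratified_kfold(separable.labels, k=5, seed=0)
        best, table = grid_search(
            separable, lambda C: LlsvmPipeline(C=C), {"C": [1.0]}, plan
        )
        assert best == {"C": 1.0}
        assert len(table) == 1

    def test_degenerate_C_not_selected(self, separable):
        """C=1e-9 forces w=0 (all-ties predictions, chance accuracy), so
        the separating C must win."""
        plan = stratified_kfold(separable.labels, k=5, seed=0)
        best, table = grid_search(
            separable, lambda C: LlsvmPipeline(C=C), {"C": [1e-9, 1.0]}, plan
        )
        assert best == {"C": 1.0}
        assert len(table) == 2
        assert table["mean_acc"].max() == 1.0

    def test_empty_grid_rejected(self, separable):
        plan = stratified_kfold(separable.labels, k=5, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(separable, lambda: None, {}, plan)
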