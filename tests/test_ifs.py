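"""Incremental feature selection: subset schedule, CV evaluation, k choice."""

import numpy as np
import pytest

from cellmark import ClassifierSpec, IFSConfig, IncrementalFeatureSelector
from cellmark.ifs import (
    build_subsets,
    evaluate_subset,
    select_feature_counts,
    stratified_folds,
)


class TestBuildSubsets:
    @pytest.mark.parametrize(
        "n, step, cap, expected",
        [
            (1000, 5, 1000, list(range(5, 1001, 5))),
            (12, 5, 1000, [5, 10, 12]),
            (3, 1, 1000, [1, 2, 3]),
            (50, 5, 12, [5, 10, 12]),
            (4, 5, 1000, [4]),
        ],
    )
    def test_schedule(self, n, step, cap, expected):
        assert build_subsets(n, step, cap) == expected

    def test_paper_scale_schedule_has_200_sizes(self):
        assert len(build_subsets(3758, 5, 1000)) == 200

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_subsets(0)


class TestSelectFeatureCounts:
    def test_worked_example(self):
        assert select_feature_counts([5, 10, 15], [0.5, 0.9, 0.92], 0.02) == (15, 10)

    def test_zero_delta_collapses_to_optimal(self):
        assert select_feature_counts([5, 10, 15], [0.5, 0.9, 0.92], 0.0) == (15, 15)

    def test_efficient_never_exceeds_optimal(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mccs = rng.random(8).tolist()
            sizes = list(range(5, 45, 5))
            opt, eff = select_feature_counts(sizes, mccs, 0.02)
            assert eff <= opt
            assert opt in sizes and eff in sizes


class TestStratifiedFolds:
    def test_every_sample_in_exactly_one_fold(self):
        y = np.array(["a"] * 23 + ["b"] * 7 + ["c"] * 3, dtype=object)
        fold = stratified_folds(y, 10, np.random.default_rng(0))
        assert fold.shape == y.shape
        assert set(fold) <= set(range(10))

    def test_class_balance_across_folds(self):
        y = np.array(["a"] * 40 + ["b"] * 20, dtype=object)
        fold = stratified_folds(y, 10, np.random.default_rng(1))
        for f in range(10):
            in_f = fold == f
            assert np.sum(in_f & (y == "a")) == 4
            assert np.sum(in_f & (y == "b")) == 2

    def test_small_class_occupies_fewer_folds(self):
        y = np.array(["a"] * 30 + ["b"] * 3, dtype=object)
        fold = stratified_folds(y, 10, np.random.default_rng(2))
        assert len(set(fold[y == "b"])) == 3


@pytest.fixture
def separable():
    rng = np.random.default_rng(5)
    y = np.array(["a"] * 60 + ["b"] * 25 + ["c"] * 15, dtype=object)
    X = rng.random((100, 4))
    X[y == "b", 0] += 10
    X[y == "c", 1] += 10
    return X, y


class TestEvaluateSubset:
    def test_separable_prefix_reaches_perfect_mcc(self, separable):
        X, y = separable
        cfg = IFSConfig(classifier=ClassifierSpec(kind="random_forest", n_trees=25), seed=0)
        mcc, acc, per_class = evaluate_subset(X, y, np.arange(2), cfg)
        assert mcc == pytest.approx(1.0)
        assert acc == 1.0
        assert all(v == 1.0 for v in per_class.values())

    def test_uninformative_constant_gene_scores_near_zero(self):
        rng = np.random.default_rng(6)
        y = rng.permutation(np.array(["a"] * 300 + ["b"] * 300, dtype=object))
        X = np.ones((600, 1))
        cfg = IFSConfig(classifier=ClassifierSpec(kind="decision_tree"), seed=0)
        mcc, _, _ = evaluate_subset(X, y, np.arange(1), cfg)
        assert abs(mcc) < 0.1

    def test_same_seed_identical_metrics(self, separable):
        X, y = separable
        cfg = IFSConfig(classifier=ClassifierSpec(kind="random_forest", n_trees=25), seed=3)
        a = evaluate_subset(X, y, np.arange(3), cfg)
        b = evaluate_subset(X, y, np.arange(3), cfg)
        assert a[:2] == b[:2]

    def test_training_folds_are_balanced_and_tests_untouched(self, separable):
        X, y = separable
        cfg = IFSConfig(classifier=ClassifierSpec(kind="decision_tree"), seed=1)
        *_, details = evaluate_subset(X, y, np.arange(2), cfg, return_details=True)
        seen = np.concatenate([d["test_idx"] for d in details])
        # pooled test folds partition the original samples exactly
        assert sorted(seen) == list(range(len(y)))
        # only training folds were augmented
        for d in details:
            assert d["n_train_synthetic"] > 0  # imbalanced input ⇒ SMOTE added samples
            assert d["n_train_original"] + len(d["test_idx"]) == len(y)


class TestIncrementalFeatureSelector:
    def test_curve_records_and_transform(self, separable):
        X, y = separable
        sel = IncrementalFeatureSelector(
            step=1, max_features=4, n_folds=5, classifier_kind="decision_tree",
            random_state=0,
        ).fit(X, y)
        ks = [r.n_features for r in sel.curve_.records]
        assert ks == [1, 2, 3, 4]
        assert sel.curve_.optimal_k == sel.optimal_k_
        assert sel.efficient_k_ <= sel.optimal_k_
        assert sel.transform(X).shape == (len(y), sel.efficient_k_)

    def test_recovery_on_planted_markers(self, chain0):
        curve = chain0["curve_rf"]
        truth = chain0["truth"]
        assert curve.max_mcc() >= 0.9
        assert curve.efficient_k <= 2 * len(truth.all_markers)
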