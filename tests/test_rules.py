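"""Rule extraction: tree/rule identity, partition, support accounting."""

import numpy as np
import pytest

from cellmark import RuleTreeClassifier, apply_rules, extract_rules, fit_final_tree
from cellmark.io import ExpressionMatrix, LabelVector
from cellmark.rules import RuleSet


@pytest.fixture
def two_class_1d():
    X = np.array([[0.0], [0.5], [1.0], [4.0], [4.5], [5.0]])
    y = np.array(["lo"] * 3 + ["hi"] * 3, dtype=object)
    m = ExpressionMatrix(X, ["g"], [f"c{i}" for i in range(6)])
    return m, LabelVector(y)


def test_separable_data_yields_depth_one_tree(two_class_1d):
    m, lab = two_class_1d
    tree = fit_final_tree(m, lab, ["g"], balance=False, seed=0)
    assert tree.get_depth() == 1
    rules = extract_rules(tree, m, lab, ["g"])
    assert len(rules.rules) == 2
    assert sum(r.support for r in rules.rules) == 6
    assert all(r.confidence == 1.0 for r in rules.rules)


def test_single_leaf_tree_gives_one_unconditional_rule():
    # constant feature: the tree cannot split
    m = ExpressionMatrix(np.ones((8, 1)), ["g"], [f"c{i}" for i in range(8)])
    lab = LabelVector(np.array(["a"] * 5 + ["b"] * 3, dtype=object))
    tree = fit_final_tree(m, lab, ["g"], balance=False, seed=0)
    rules = extract_rules(tree, m, lab, ["g"])
    assert len(rules.rules) == 1
    assert rules.rules[0].conditions == []
    assert rules.rules[0].support == 8


def test_single_class_input_errors():
    from cellmark.rules import _fit_tree_array

    with pytest.raises(ValueError, match="2 classes"):
        _fit_tree_array(np.ones((4, 1)), np.array(["x"] * 4), False, 0, 5)


def test_rules_reproduce_tree_predictions_exactly():
    rng = np.random.default_rng(0)
    X = rng.random((120, 3)) * 5
    y = np.where(X[:, 0] + X[:, 1] > 5, "A", np.where(X[:, 2] > 2.5, "B", "C")).astype(object)
    m = ExpressionMatrix(X, ["g0", "g1", "g2"], [f"c{i}" for i in range(120)])
    lab = LabelVector(y)
    tree = fit_final_tree(m, lab, ["g0", "g1", "g2"], balance=False, seed=1)
    rules = extract_rules(tree, m, lab, ["g0", "g1", "g2"])
    tree_pred = tree.predict(X)
    for row, expect in zip(X, tree_pred):
        assert apply_rules(rules, dict(zip(["g0", "g1", "g2"], row))) == str(expect)
    assert sum(r.support for r in rules.rules) == 120


def test_exactly_one_rule_fires_per_grid_point():
    rng = np.random.default_rng(2)
    X = rng.random((60, 2)) * 4
    y = (X[:, 0] > 2).astype(int).astype(str)
    clf = RuleTreeClassifier(balance=False, feature_names=["u", "v"], random_state=0)
    clf.fit(X, y)
    grid = np.stack(np.meshgrid(np.linspace(0, 4, 15), np.linspace(0, 4, 15)), -1).reshape(-1, 2)
    for point in grid:
        matches = [r for r in clf.rules_.rules if r.matches({"u": point[0], "v": point[1]})]
        assert len(matches) == 1


def test_threshold_boundary_follows_tree_semantics(two_class_1d):
    m, lab = two_class_1d
    tree = fit_final_tree(m, lab, ["g"], balance=False, seed=0)
    rules = extract_rules(tree, m, lab, ["g"])
    thr = rules.rules[0].conditions[0][2]
    # a sample exactly at θ satisfies "g ≤ θ" and takes the left branch,
    # exactly as tree.predict does
    assert apply_rules(rules, {"g": thr}) == str(tree.predict([[thr]])[0])


def test_unbalanced_final_tree_favours_majority_leaves():
    # coarse discrete features keep classes mixed inside every leaf, so
    # under a 15:1 ratio the majority label dominates the leaf votes
    rng = np.random.default_rng(3)
    y = np.array(["maj"] * 180 + ["min"] * 12, dtype=object)
    X = rng.integers(0, 4, size=(192, 2)).astype(float)
    m = ExpressionMatrix(X, ["g0", "g1"], [f"c{i}" for i in range(192)])
    lab = LabelVector(y)
    tree = fit_final_tree(m, lab, ["g0", "g1"], balance=False, seed=0)
    rules = extract_rules(tree, m, lab, ["g0", "g1"])
    preds = [r.predicted_class for r in rules.rules]
    assert preds.count("maj") > preds.count("min")


def test_rule_sorting_and_cap():
    rng = np.random.default_rng(4)
    X = rng.random((200, 2)) * 8
    y = ((X[:, 0] > 4).astype(int) + 2 * (X[:, 1] > 4).astype(int)).astype(str)
    m = ExpressionMatrix(X, ["a", "b"], [f"c{i}" for i in range(200)])
    lab = LabelVector(y)
    tree = fit_final_tree(m, lab, ["a", "b"], balance=False, seed=0)
    rules = extract_rules(tree, m, lab, ["a", "b"], top_n=2)
    supports = [r.support for r in rules.rules]
    assert supports == sorted(supports, reverse=True)
    assert rules.n_extracted == 2
    assert len(rules.top()) == 2


def test_corrupted_rule_set_detected():
    rs = RuleSet(rules=[], n_extracted=0)
    with pytest.raises(ValueError, match="no rule matches"):
        apply_rules(rs, {"g": 1.0})


def test_rule_classifier_predict_matches_tree(two_class_1d):
    m, lab = two_class_1d
    clf = RuleTreeClassifier(balance=False, feature_names=["g"], random_state=0)
    clf.fit(m.values, lab.labels)
    np.testing.assert_array_equal(
        clf.predict(m.values).astype(str), clf.tree_model_.predict(m.values).astype(str)
    )
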