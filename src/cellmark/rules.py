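"""IF–THEN decision rules from a single decision tree.

The final interpretable model is one entropy-criterion tree fit on the
optimal feature prefix (optionally SMOTE-balanced).  Each leaf yields one
rule: the conjunction of the gene ≤ θ / gene > θ conditions along its
root-to-leaf path, predicting the leaf's majority class.  Support and
confidence are counted on the *original* (pre-balancing) cells so reported
patterns describe real data; rules from one tree are mutually exclusive
and exhaustive, so exactly one rule fires for any sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import ExpressionMatrix, LabelVector
from .smote import SMOTEOversampler


@dataclass
class DecisionRule:
    """Conjunction of threshold conditions → class, with its support
    (original samples satisfying all conditions) and confidence (fraction
    of those with the predicted class)."""

    conditions: list[tuple[str, str, float]]  # (gene_id, "<=" or ">", threshold)
    predicted_class: str
    support: int
    confidence: float

    def matches(self, sample: Mapping[str, float]) -> bool:
        for gene, op, thr in self.conditions:
            v = sample[gene]
            if op == "<=":
                if not v <= thr:
                    return False
            elif op == ">":
                if not v > thr:
                    return False
            else:
                raise ValueError(f"unknown operator {op!r}")
        return True


@dataclass
class RuleSet:
    """Rules of one tree, sorted by support then confidence; ``rules``
    holds the full partition, ``n_extracted`` caps what is exported."""

    rules: list[DecisionRule]
    n_extracted: int = 0

    def top(self) -> list[DecisionRule]:
        return self.rules[: self.n_extracted]


def _fit_tree_array(X, y, balance: bool, seed: int, k_neighbors: int) -> DecisionTreeClassifier:
    if len(np.unique(y)) < 2:
        raise ValueError("need ≥ 2 classes to fit the final tree")
    if balance:
        X, y = SMOTEOversampler(k_neighbors=k_neighbors, random_state=seed).fit_resample(X, y)
    return DecisionTreeClassifier(criterion="entropy", random_state=seed).fit(X, y)


def _extract_rules_array(
    tree: DecisionTreeClassifier,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    top_n: int,
) -> RuleSet:
    t = tree.tree_
    class_names = [str(c) for c in tree.classes_]
    y = np.asarray(y).astype(str)
    leaf_of = tree.apply(np.asarray(X, dtype=float))

    keyed: list[tuple[int, float, int, DecisionRule]] = []
    order = 0
    stack: list[tuple[int, list[tuple[str, str, float]]]] = [(0, [])]
    while stack:
        node, conds = stack.pop()
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            pred = class_names[int(np.argmax(t.value[node]))]
            here = leaf_of == node
            support = int(here.sum())
            confidence = float(np.mean(y[here] == pred)) if support else 0.0
            keyed.append((support, confidence, order, DecisionRule(list(conds), pred, support, confidence)))
            order += 1
            continue
        gene = feature_names[int(t.feature[node])]
        thr = float(t.threshold[node])
        stack.append((right, conds + [(gene, ">", thr)]))
        stack.append((left, conds + [(gene, "<=", thr)]))
    keyed.sort(key=lambda k: (-k[0], -k[1], k[2]))
    rules = [r for *_, r in keyed]
    return RuleSet(rules=rules, n_extracted=min(top_n, len(rules)))


def fit_final_tree(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    feature_prefix: Sequence[str],
    balance: bool = True,
    seed: int = 0,
    k_neighbors: int = 5,
) -> DecisionTreeClassifier:
    """Fit the single interpretable tree on the whole dataset restricted to
    ``feature_prefix`` (SMOTE-balanced when ``balance``)."""
    sub = matrix.subset_genes(feature_prefix)
    return _fit_tree_array(sub.values, labels.labels, balance, seed, k_neighbors)


def extract_rules(
    tree: DecisionTreeClassifier,
    matrix: ExpressionMatrix,
    labels: LabelVector,
    feature_prefix: Sequence[str],
    top_n: int = 1000,
) -> RuleSet:
    """One rule per leaf; support/confidence counted on the original
    samples in ``matrix``/``labels`` (never on synthetic copies)."""
    sub = matrix.subset_genes(feature_prefix)
    return _extract_rules_array(tree, sub.values, labels.labels, list(feature_prefix), top_n)


def apply_rules(rules: RuleSet, sample: Mapping[str, float]) -> str:
    """Predict by the unique matching rule (rules of one tree partition the
    feature space); a missing match indicates a corrupted rule set."""
    for rule in rules.rules:
        if rule.matches(sample):
            return rule.predicted_class
    raise ValueError("no rule matches the sample: rule set is not exhaustive")


class RuleTreeClassifier(ClassifierMixin, BaseEstimator):
    """Interpretable classifier: a single entropy-criterion tree whose
    predictions are served through its extracted IF–THEN rule set.

    After ``fit``: ``tree_model_`` (the sklearn tree), ``rules_`` (RuleSet),
    ``feature_names_``.
    """

    def __init__(self, balance: bool = True, top_n: int = 1000,
                 k_neighbors: int = 5, feature_names: list[str] | None = None,
                 random_state: int = 0):
        self.balance = balance
        self.top_n = top_n
        self.k_neighbors = k_neighbors
        self.feature_names = feature_names
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        names = list(self.feature_names) if self.feature_names else [
            f"f{j}" for j in range(X.shape[1])
        ]
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.tree_model_ = _fit_tree_array(
            X, y, balance=self.balance, seed=self.random_state,
            k_neighbors=self.k_neighbors,
        )
        self.classes_ = self.tree_model_.classes_
        self.rules_ = _extract_rules_array(self.tree_model_, X, y, names, self.top_n)
        self.feature_names_ = names
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "rules_")
        X = np.asarray(X, dtype=float)
        out = [
            apply_rules(self.rules_, dict(zip(self.feature_names_, row)))
            for row in X
        ]
        return np.asarray(out, dtype=object)
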