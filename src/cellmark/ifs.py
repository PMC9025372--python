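"""Incremental feature selection over a ranked feature list.

Nested top-k prefixes of the ranked list (k = step, 2·step, …, up to a
cap) are each evaluated with stratified 10-fold cross-validation: the
training fold is SMOTE-balanced, the classifier (random forest or a
single decision tree) is fit on it, and the untouched test fold is
predicted.  Out-of-fold predictions are pooled and scored with the
multiclass MCC, overall accuracy and per-class recall.  The *optimal*
feature count is the smallest k attaining the maximum MCC; the
*efficient* count is the smallest k whose MCC is within ``delta`` of that
maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y

from .io import ExpressionMatrix, LabelVector, RankedFeatureList
from .metrics import multiclass_mcc, overall_accuracy, per_class_accuracy
from .smote import SMOTEOversampler

logger = logging.getLogger(__name__)


@dataclass
class ClassifierSpec:
    """Classifier contract for IFS: random forest (majority vote of its
    trees) or a single axis-aligned decision tree."""

    kind: str = "random_forest"
    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0

    def build(self, seed: int | None = None):
        seed = self.seed if seed is None else seed
        if self.kind in ("random_forest", "rf"):
            return RandomForestClassifier(
                n_estimators=self.n_trees, max_depth=self.max_depth,
                random_state=seed, n_jobs=1,
            )
        if self.kind in ("decision_tree", "dt"):
            return DecisionTreeClassifier(
                criterion="entropy", max_depth=self.max_depth, random_state=seed
            )
        raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class IFSConfig:
    step: int = 5
    max_features: int = 1000
    n_folds: int = 10
    delta: float = 0.02
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k_neighbors: int = 5          # SMOTE neighbourhood
    balance: bool = True          # SMOTE the training folds
    balance_before_cv: bool = False  # leaky variant, for comparison only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be ≥ 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be ≥ 2")
        if self.delta < 0:
            raise ValueError("delta must be ≥ 0")


@dataclass
class IFSRecord:
    n_features: int
    mcc: float
    acc: float
    per_class: dict[str, float]


@dataclass
class IFSCurve:
    records: list[IFSRecord]
    optimal_k: int
    efficient_k: int

    def __post_init__(self) -> None:
        ks = [r.n_features for r in self.records]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("n_features must be strictly increasing")
        if self.records and (self.optimal_k not in ks or self.efficient_k not in ks):
            raise ValueError("optimal_k and efficient_k must appear among the records")

    def max_mcc(self) -> float:
        return max(r.mcc for r in self.records)


def build_subsets(n_ranked: int, step: int = 5, max_features: int = 1000) -> list[int]:
    """Prefix sizes step, 2·step, … up to min(n_ranked, max_features); a
    non-multiple bound is appended as a final partial prefix."""
    if n_ranked < 1:
        raise ValueError("ranked list is empty")
    bound = min(n_ranked, max_features)
    sizes = list(range(step, bound + 1, step))
    if not sizes or sizes[-1] != bound:
        sizes.append(bound)
    return sizes


def select_feature_counts(sizes: list[int], mccs: list[float], delta: float) -> tuple[int, int]:
    """(optimal_k, efficient_k): smallest size attaining the maximum MCC,
    and smallest size with MCC ≥ max − delta."""
    if len(sizes) != len(mccs) or not sizes:
        raise ValueError("sizes and mccs must be equal-length and non-empty")
    arr = np.asarray(mccs, dtype=float)
    best = float(arr.max())
    optimal_k = sizes[int(np.flatnonzero(arr == best)[0])]
    efficient_k = sizes[int(np.flatnonzero(arr >= best - delta)[0])]
    return optimal_k, efficient_k


def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per sample: within each class, shuffled round-robin
    assignment.  Classes smaller than ``n_folds`` simply occupy fewer
    folds, so every sample still appears in exactly one test fold."""
    fold = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        if len(idx) < n_folds:
            logger.info("class %r has %d < %d samples; present in fewer folds",
                        c, len(idx), n_folds)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    feature_prefix: np.ndarray,
    config: IFSConfig,
    return_details: bool = False,
):
    """Cross-validate one feature prefix; returns (mcc, acc, per_class)
    from pooled out-of-fold predictions.

    With ``return_details`` a dict with per-fold test indices and the
    original/synthetic composition of each training set is also returned
    (provenance audit: test folds contain only original samples by
    construction — predictions are made on rows of X itself).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel().astype(object)
    rng = np.random.default_rng(config.seed)
    Xp = X[:, feature_prefix]

    if config.balance and config.balance_before_cv:
        # leaky variant: synthetic samples participate in the folds
        sampler = SMOTEOversampler(k_neighbors=config.k_neighbors,
                                   random_state=int(rng.integers(2**31 - 1)))
        Xp, y = sampler.fit_resample(Xp, y)
        y = np.asarray(y, dtype=object)

    fold = stratified_folds(y, config.n_folds, rng)
    pred = np.empty(len(y), dtype=object)
    details = []
    for f in range(config.n_folds):
        te = np.flatnonzero(fold == f)
        tr = np.flatnonzero(fold != f)
        if len(te) == 0:
            continue
        Xtr, ytr = Xp[tr], y[tr]
        n_orig = len(tr)
        if config.balance and not config.balance_before_cv:
            sampler = SMOTEOversampler(k_neighbors=config.k_neighbors,
                                       random_state=int(rng.integers(2**31 - 1)))
            Xtr, ytr = sampler.fit_resample(Xtr, ytr)
        clf = config.classifier.build(seed=int(rng.integers(2**31 - 1)))
        clf.fit(Xtr, ytr)
        pred[te] = clf.predict(Xp[te])
        details.append({
            "test_idx": te,
            "n_train_original": n_orig,
            "n_train_synthetic": len(ytr) - n_orig,
        })
    mcc = multiclass_mcc(y, pred)
    acc = overall_accuracy(y, pred)
    per_class = per_class_accuracy(y, pred)
    if return_details:
        return mcc, acc, per_class, details
    return mcc, acc, per_class


def run_ifs(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    ranked: RankedFeatureList,
    config: IFSConfig | None = None,
) -> IFSCurve:
    """Sweep the ranked-list prefixes and select the optimal and efficient
    feature counts."""
    config = config or IFSConfig()
    sub = matrix.subset_genes(ranked.gene_ids)
    sel = IncrementalFeatureSelector(
        step=config.step, max_features=config.max_features, n_folds=config.n_folds,
        delta=config.delta, classifier_kind=config.classifier.kind,
        n_trees=config.classifier.n_trees, max_depth=config.classifier.max_depth,
        k_neighbors=config.k_neighbors, balance=config.balance,
        balance_before_cv=config.balance_before_cv, random_state=config.seed,
    ).fit(sub.values, labels.labels)
    return sel.curve_


class IncrementalFeatureSelector(BaseEstimator):
    """sklearn-style wrapper: fit sweeps the prefixes of the column order
    (assumed already ranked), exposing ``curve_``, ``optimal_k_`` and
    ``efficient_k_``; transform keeps the efficient prefix columns."""

    def __init__(self, step: int = 5, max_features: int = 1000, n_folds: int = 10,
                 delta: float = 0.02, classifier_kind: str = "random_forest",
                 n_trees: int = 100, max_depth: int | None = None,
                 k_neighbors: int = 5, balance: bool = True,
                 balance_before_cv: bool = False, random_state: int = 0):
        self.step = step
        self.max_features = max_features
        self.n_folds = n_folds
        self.delta = delta
        self.classifier_kind = classifier_kind
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.k_neighbors = k_neighbors
        self.balance = balance
        self.balance_before_cv = balance_before_cv
        self.random_state = random_state

    def _config(self) -> IFSConfig:
        return IFSConfig(
            step=self.step, max_features=self.max_features, n_folds=self.n_folds,
            delta=self.delta,
            classifier=ClassifierSpec(kind=self.classifier_kind, n_trees=self.n_trees,
                                      max_depth=self.max_depth, seed=self.random_state),
            k_neighbors=self.k_neighbors, balance=self.balance,
            balance_before_cv=self.balance_before_cv, seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        config = self._config()
        sizes = build_subsets(X.shape[1], config.step, config.max_features)
        records = []
        for k in sizes:
            mcc, acc, per_class = evaluate_subset(X, y, np.arange(k), config)
            records.append(IFSRecord(n_features=k, mcc=mcc, acc=acc, per_class=per_class))
        optimal_k, efficient_k = select_feature_counts(
            sizes, [r.mcc for r in records], config.delta
        )
        self.curve_ = IFSCurve(records=records, optimal_k=optimal_k, efficient_k=efficient_k)
        self.optimal_k_ = optimal_k
        self.efficient_k_ = efficient_k
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, : self.efficient_k_]
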