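"""Monte Carlo feature selection: relative-importance ranking.

s random projections of m features are drawn from the d candidates; on
each projection t decision trees are trained on independent stratified
train/test resplits.  A feature f accumulates, over every node n of every
tree τ that splits on f,

    RI_f = Σ_τ  wAcc(τ)^u · IG(n_f(τ)) · (samples reaching n / samples in τ)^v

where wAcc is the tree's weighted accuracy (mean per-class recall on its
held-out split), IG is the node's information gain (entropy criterion, so
in bits) and u, v default to 1.  Features are returned in decreasing RI
order; ties keep the original gene order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y

from .io import ExpressionMatrix, LabelVector, RankedFeatureList

logger = logging.getLogger(__name__)


@dataclass
class MCFSConfig:
    """m = projection size (default ⌈0.05·d⌉, ≥1); s = number of
    projections (default ⌈300·d/m⌉ capped at 20,000); t = trees per
    projection; u, v = RI exponents on wAcc and the node fraction."""

    m: int | None = None
    s: int | None = None
    t: int = 5
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 0.66
    seed: int = 0

    def resolve(self, d: int) -> tuple[int, int, int]:
        m = self.m if self.m is not None else max(1, math.ceil(0.05 * d))
        if not (1 <= m <= d):
            raise ValueError(f"projection size m={m} outside [1, {d}]")
        s = self.s if self.s is not None else min(20_000, math.ceil(300 * d / m))
        if s < 1 or self.t < 1:
            raise ValueError("s and t must be ≥ 1")
        if self.u < 0 or self.v < 0:
            raise ValueError("u and v must be ≥ 0")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        return m, s, self.t


@dataclass
class TreeRecord:
    """One evaluated tree: held-out weighted accuracy plus, per feature,
    the (information gain, node sample fraction) of each node splitting
    on it."""

    wacc: float
    node_contribs: dict[int, list[tuple[float, float]]] = field(default_factory=dict)


def draw_projection(d: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform m-subset of the d feature indices, without replacement."""
    if not (1 <= m <= d):
        raise ValueError(f"need 1 ≤ m ≤ d, got m={m}, d={d}")
    return np.sort(rng.choice(d, size=m, replace=False))


def _stratified_split(y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """Per-class split; every class with ≥2 samples keeps at least one
    sample on each side, singletons go to train."""
    train, test = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        if len(idx) == 1:
            train.extend(idx)
            continue
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.sort(np.asarray(train, dtype=int)), np.sort(np.asarray(test, dtype=int))


def _tree_contribs(tree: DecisionTreeClassifier, feature_idx: np.ndarray) -> dict:
    """Per-feature (IG, node fraction) pairs from a fitted entropy tree.

    IG(n) = H(n) − Σ_children (w_child / w_n) · H(child); node fraction is
    w_n over the training-sample count at the root.
    """
    t = tree.tree_
    contribs: dict[int, list[tuple[float, float]]] = {}
    w = t.weighted_n_node_samples
    root_w = w[0]
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            continue
        ig = t.impurity[node] - (
            w[left] / w[node] * t.impurity[left] + w[right] / w[node] * t.impurity[right]
        )
        ig = max(ig, 0.0)
        f_global = int(feature_idx[t.feature[node]])
        contribs.setdefault(f_global, []).append((float(ig), float(w[node] / root_w)))
    return contribs


def evaluate_tree(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
    max_attempts: int = 10,
) -> TreeRecord | None:
    """Fit one entropy decision tree on a stratified resplit of the
    projected data; returns None (with a warning) if no usable split is
    found in ``max_attempts`` draws."""
    for _ in range(max_attempts):
        tr, te = _stratified_split(y, train_fraction, rng)
        if len(np.unique(y[tr])) >= 2 and len(te) > 0:
            break
    else:
        logger.warning("skipping projection: degenerate train/test split")
        return None
    tree = DecisionTreeClassifier(
        criterion="entropy", random_state=int(rng.integers(2**31 - 1))
    ).fit(X[np.ix_(tr, feature_idx)], y[tr])
    pred = tree.predict(X[np.ix_(te, feature_idx)])
    # wAcc: unweighted mean of per-class recall over classes present in test
    recalls = [
        float(np.mean(pred[y[te] == c] == c)) for c in np.unique(y[te])
    ]
    return TreeRecord(wacc=float(np.mean(recalls)), node_contribs=_tree_contribs(tree, feature_idx))


def relative_importance(
    records: list[TreeRecord], d: int, u: float = 1.0, v: float = 1.0
) -> np.ndarray:
    """Aggregate RI scores over all evaluated trees (features absent from
    every tree get 0)."""
    if not records:
        raise ValueError("no tree records")
    ri = np.zeros(d)
    for rec in records:
        w = rec.wacc ** u
        for f, pairs in rec.node_contribs.items():
            ri[f] += w * sum(ig * frac ** v for ig, frac in pairs)
    return ri


class MCFSRanker(BaseEstimator):
    """Rank features by Monte Carlo relative importance.

    Attributes
    ----------
    ri_scores_ : ndarray of shape (n_features,)
    ranking_ : feature indices in decreasing RI order (ties keep input order)
    records_ : the evaluated TreeRecords (only when ``store_records``)
    n_trees_evaluated_ : number of (projection, resplit) tree fits kept
    """

    def __init__(self, m: int | None = None, s: int | None = None, t: int = 5,
                 u: float = 1.0, v: float = 1.0, train_fraction: float = 0.66,
                 store_records: bool = False, random_state: int = 0):
        self.m = m
        self.s = s
        self.t = t
        self.u = u
        self.v = v
        self.train_fraction = train_fraction
        self.store_records = store_records
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        cfg = MCFSConfig(m=self.m, s=self.s, t=self.t, u=self.u, v=self.v,
                         train_fraction=self.train_fraction, seed=self.random_state)
        d = X.shape[1]
        m, s, t = cfg.resolve(d)
        rng = np.random.default_rng(self.random_state)
        records: list[TreeRecord] = []
        for _ in range(s):
            proj = draw_projection(d, m, rng)
            for _ in range(t):
                rec = evaluate_tree(X, y, proj, cfg.train_fraction, rng)
                if rec is not None:
                    records.append(rec)
        self.ri_scores_ = relative_importance(records, d, cfg.u, cfg.v)
        self.ranking_ = np.argsort(-self.ri_scores_, kind="stable")
        self.n_trees_evaluated_ = len(records)
        if self.store_records:
            self.records_ = records
        self.n_features_in_ = d
        return self

    def transform(self, X):
        """Columns reordered by decreasing relative importance."""
        X = np.asarray(X)
        return X[:, self.ranking_]


def run_mcfs(
    matrix: ExpressionMatrix, labels: LabelVector, config: MCFSConfig | None = None
) -> RankedFeatureList:
    """Rank the genes of an ExpressionMatrix (typically already restricted
    to the shadow-feature survivors) by RI score."""
    config = config or MCFSConfig()
    ranker = MCFSRanker(
        m=config.m, s=config.s, t=config.t, u=config.u, v=config.v,
        train_fraction=config.train_fraction, random_state=config.seed,
    ).fit(matrix.values, labels.labels)
    return RankedFeatureList(
        [(matrix.gene_ids[j], float(ranker.ri_scores_[j])) for j in ranker.ranking_]
    )
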