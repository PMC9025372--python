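"""Maximum-relevance filtering: mutual information of each gene with the
cell-type label.

Continuous expression values are discretized into three states
(low / mid / high) around the gene's mean ± α·σ — the preprocessing used by
the classic mRMR family of filters — and the MI of the discretized gene
with the label is the plug-in estimate from the joint frequency table, in
bits.  Genes whose MI exceeds a small threshold (default 0.001) are
retained; only the relevance term is used, never a redundancy penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import ExpressionMatrix, LabelVector

LOW, MID, HIGH = 0, 1, 2


@dataclass
class DiscretizationScheme:
    """Three-state mean ± α·σ binning of a continuous feature."""

    kind: str = "three_state_sigma"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.kind != "three_state_sigma":
            raise ValueError(f"unknown discretization kind {self.kind!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class RelevanceResult:
    """Per-gene MI scores and the retained (MI > threshold) gene list."""

    mi_scores: dict[str, float]
    retained: list[str]
    threshold: float


def discretize_gene(values: np.ndarray, scheme: DiscretizationScheme | None = None) -> np.ndarray:
    """Map a value vector to states {low, mid, high} around mean ± α·σ.

    σ uses denominator n (population form); a constant vector has σ = 0 and
    maps entirely to mid.
    """
    scheme = scheme or DiscretizationScheme()
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    mean = v.mean()
    sd = v.std()  # ddof = 0
    states = np.full(v.shape, MID, dtype=np.int8)
    states[v < mean - scheme.alpha * sd] = LOW
    states[v > mean + scheme.alpha * sd] = HIGH
    return states


def mutual_information(x_states, y_labels) -> float:
    """Plug-in mutual information of two categorical vectors, in bits.

    I(x, y) = Σ p̂(x,y) log2( p̂(x,y) / (p̂(x) p̂(y)) ), with zero-probability
    cells contributing 0.  Symmetric and non-negative (up to rounding).
    """
    x = np.asarray(x_states).ravel()
    y = np.asarray(y_labels).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.size == 0:
        raise ValueError("empty input")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return float(np.nansum(terms))


class MaxRelevanceFilter(SelectorMixin, BaseEstimator):
    """Keep genes whose MI with the label strictly exceeds ``threshold``.

    Parameters
    ----------
    threshold : float, default 0.001
        Retention cutoff in bits; a feature is kept iff MI > threshold.
    alpha : float, default 1.0
        Width multiplier of the mean ± α·σ discretization.
    keep_all_if_empty : bool, default False
        If no gene passes, keep all genes (with a warning) instead of
        returning an empty selection.

    Attributes
    ----------
    mi_scores_ : ndarray of shape (n_features,)
        MI of each (discretized) feature with the label, in bits.
    support_ : ndarray of bool
        Mask of retained features, original order preserved.
    """

    def __init__(self, threshold: float = 0.001, alpha: float = 1.0,
                 keep_all_if_empty: bool = False):
        self.threshold = threshold
        self.alpha = alpha
        self.keep_all_if_empty = keep_all_if_empty

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        if self.threshold < 0:
            raise ValueError("threshold must be ≥ 0")
        scheme = DiscretizationScheme(alpha=self.alpha)
        self.mi_scores_ = np.array(
            [mutual_information(discretize_gene(X[:, j], scheme), y) for j in range(X.shape[1])]
        )
        self.support_ = self.mi_scores_ > self.threshold
        if not self.support_.any():
            warnings.warn("no feature exceeds the MI threshold", UserWarning)
            if self.keep_all_if_empty:
                self.support_ = np.ones(X.shape[1], dtype=bool)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def max_relevance_filter(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    threshold: float = 0.001,
    scheme: DiscretizationScheme | None = None,
    keep_all_if_empty: bool = False,
) -> RelevanceResult:
    """Score every gene and retain those with MI > threshold (gene order
    preserved)."""
    scheme = scheme or DiscretizationScheme()
    if len(labels) != matrix.n_cells:
        raise ValueError("matrix and labels are not aligned")
    f = MaxRelevanceFilter(
        threshold=threshold, alpha=scheme.alpha, keep_all_if_empty=keep_all_if_empty
    ).fit(matrix.values, labels.labels)
    scores = {g: float(s) for g, s in zip(matrix.gene_ids, f.mi_scores_)}
    retained = [g for g, keep in zip(matrix.gene_ids, f.support_) if keep]
    return RelevanceResult(mi_scores=scores, retained=retained, threshold=threshold)
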