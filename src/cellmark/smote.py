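"""SMOTE oversampling: balance all classes up to the majority count.

A synthetic minority sample is a random convex combination
z = x + λ·(y − x), λ ~ U(0, 1), of a minority sample x and one of its k
nearest same-class neighbours y (Euclidean distance).  Originals are
preserved and ordered first in the output; the pipeline applies this only
to cross-validation *training* folds so that held-out folds contain real
cells only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, LabelVector


@dataclass
class SMOTEConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be ≥ 1")


class SMOTEOversampler(BaseEstimator):
    """Oversample every minority class to the majority count.

    Parameters
    ----------
    k_neighbors : int, default 5
        Neighbourhood size; clamped (with a warning) to class size − 1.
    random_state : int, default 0

    Attributes (after ``fit_resample``)
    ----------
    synthetic_ : ndarray of bool, aligned to the resampled rows
        False for original samples, True for synthetic ones.
    parents_ : ndarray of shape (n_synthetic, 2)
        Row indices (into the input X) of the two parents of each
        synthetic sample, in emission order.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y, lam: float | None = None):
        """Return (X_res, y_res) with equal class counts.

        ``lam`` overrides the Uniform(0,1) interpolation weight with a
        fixed value (testing hook; ``lam=0`` duplicates parents).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y are misaligned")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be ≥ 1")
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_max = counts.max()

        new_rows: list[np.ndarray] = []
        new_labels: list = []
        parents: list[tuple[int, int]] = []
        for c, n_c in zip(classes, counts):
            need = int(n_max - n_c)
            if need == 0:
                continue
            if n_c < 2:
                raise ValueError(f"class {c!r} has a single sample; SMOTE needs ≥ 2")
            idx = np.flatnonzero(y == c)
            k = self.k_neighbors
            if k > n_c - 1:
                warnings.warn(
                    f"k_neighbors={k} clamped to {n_c - 1} for class {c!r}", UserWarning
                )
                k = int(n_c - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X[idx])
            # column 0 is the sample itself
            neigh = nn.kneighbors(X[idx], return_distance=False)[:, 1:]
            xi = rng.integers(0, n_c, size=need)
            yi = neigh[xi, rng.integers(0, k, size=need)]
            lams = np.full(need, lam, dtype=float) if lam is not None else rng.random(need)
            a = X[idx[xi]]
            b = X[idx[yi]]
            new_rows.append(a + lams[:, None] * (b - a))
            new_labels.extend([c] * need)
            parents.extend(zip(idx[xi].tolist(), idx[yi].tolist()))

        if new_rows:
            X_res = np.vstack([X, *new_rows])
            y_res = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
        else:
            X_res, y_res = X.copy(), y.copy()
        self.synthetic_ = np.concatenate(
            [np.zeros(X.shape[0], dtype=bool), np.ones(X_res.shape[0] - X.shape[0], dtype=bool)]
        )
        self.parents_ = np.asarray(parents, dtype=int).reshape(-1, 2)
        return X_res, y_res


def smote_balance(
    matrix: ExpressionMatrix,
    labels: LabelVector,
    config: SMOTEConfig | None = None,
    lam: float | None = None,
) -> tuple[ExpressionMatrix, LabelVector]:
    """Balance an ExpressionMatrix/LabelVector pair; synthetic cells get
    ``synth_<i>`` identifiers appended after the originals."""
    config = config or SMOTEConfig()
    sampler = SMOTEOversampler(k_neighbors=config.k_neighbors, random_state=config.seed)
    X_res, y_res = sampler.fit_resample(matrix.values, labels.labels, lam=lam)
    n_new = X_res.shape[0] - matrix.n_cells
    cell_ids = list(matrix.cell_ids) + [f"synth_{i:06d}" for i in range(n_new)]
    out_m = ExpressionMatrix(X_res, list(matrix.gene_ids), cell_ids)
    out_l = LabelVector(y_res, classes=list(labels.classes))
    return out_m, out_l
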