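"""Shadow-feature (all-relevant) selection.

Each candidate gene competes against "shadows" — column-wise permuted
copies of every candidate — inside a random-forest importance ranking.
Per iteration the shadows are re-shuffled, a forest is fit on the
originals + shadows, and every non-rejected gene scores a *hit* when its
impurity-decrease importance exceeds the best shadow importance.  Hit
counts are tested against Binomial(n_iterations, 1/2): significantly many
hits confirms a gene, significantly few rejects it (rejected genes leave
the design matrix).  Genes still undecided at ``max_iter`` stay tentative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .io import ExpressionMatrix, LabelVector

UNDECIDED, CONFIRMED, REJECTED = 0, 1, -1


@dataclass
class BorutaConfig:
    max_iter: int = 100
    alpha: float = 0.05
    n_trees: int = 100
    two_step_correction: bool = True
    include_tentative: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be ≥ 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BorutaResult:
    confirmed: set[str]
    rejected: set[str]
    tentative: set[str]
    hit_history: dict[str, list[bool]] = field(default_factory=dict)


def make_shadows(matrix: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Append a per-column independently permuted copy of every gene,
    named ``shadow_<gene>``."""
    if matrix.n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    shadows = _shadow_columns(matrix.values, rng)
    values = np.hstack([matrix.values, shadows])
    names = list(matrix.gene_ids) + [f"shadow_{g}" for g in matrix.gene_ids]
    return ExpressionMatrix(values, names, list(matrix.cell_ids))


def _shadow_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = rng.permutation(X[:, j])
    return out


def _fdr_pass(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up: boolean mask of hypotheses rejected
    (i.e. significant) at FDR level alpha."""
    m = len(pvals)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvals)
    ranked = pvals[order]
    thresh = alpha * (np.arange(1, m + 1) / m)
    below = ranked <= thresh
    passed = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = np.max(np.flatnonzero(below))
        passed[order[: cutoff + 1]] = True
    return passed


class BorutaSelector(SelectorMixin, BaseEstimator):
    """All-relevant feature selection against shuffled shadow features.

    The multiplicity handling follows the reference two-step scheme when
    ``two_step_correction=True``: per iteration, confirmation/rejection
    requires both a Benjamini–Hochberg pass across the candidate features
    and a Bonferroni-across-iterations pass (p ≤ alpha / iteration).  With
    ``two_step_correction=False`` a plain Bonferroni across features
    (p ≤ alpha / n_features) is used instead.

    Attributes
    ----------
    decision_ : ndarray of {1, 0, -1}  (confirmed / tentative / rejected)
    hit_history_ : list of per-iteration boolean hit arrays over features
    hits_, trials_ : cumulative hit counts and trial counts per feature
    n_iter_ : iterations actually run
    support_ : confirmed genes, plus tentative ones when
        ``include_tentative`` is set.
    """

    def __init__(self, max_iter: int = 100, alpha: float = 0.05, n_trees: int = 100,
                 two_step_correction: bool = True, include_tentative: bool = True,
                 random_state: int = 0):
        self.max_iter = max_iter
        self.alpha = alpha
        self.n_trees = n_trees
        self.two_step_correction = two_step_correction
        self.include_tentative = include_tentative
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        cfg = BorutaConfig(
            max_iter=self.max_iter, alpha=self.alpha, n_trees=self.n_trees,
            two_step_correction=self.two_step_correction,
            include_tentative=self.include_tentative, seed=self.random_state,
        )
        n, d = X.shape
        n_classes = len(np.unique(y))
        if n_classes < 2:
            raise ValueError("need ≥ 2 classes")
        if n < n_classes:
            raise ValueError("fewer cells than classes")
        rng = np.random.default_rng(self.random_state)

        decision = np.zeros(d, dtype=int)
        hits = np.zeros(d, dtype=int)
        trials = np.zeros(d, dtype=int)
        history: list[np.ndarray] = []

        for it in range(1, cfg.max_iter + 1):
            active = decision != REJECTED  # confirmed genes stay in the model
            act_idx = np.flatnonzero(active)
            Xa = X[:, act_idx]
            shadows = _shadow_columns(Xa, rng)
            rf = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            ).fit(np.hstack([Xa, shadows]), y)
            imp = rf.feature_importances_
            real_imp = imp[: len(act_idx)]
            shadow_max = imp[len(act_idx):].max()

            hit_now = np.zeros(d, dtype=bool)
            hit_now[act_idx] = real_imp > shadow_max
            hits[act_idx] += hit_now[act_idx]
            trials[act_idx] += 1
            history.append(hit_now)

            und = np.flatnonzero(decision == UNDECIDED)
            if len(und):
                p_hi = binom.sf(hits[und] - 1, trials[und], 0.5)  # P[H ≥ hits]
                p_lo = binom.cdf(hits[und], trials[und], 0.5)     # P[H ≤ hits]
                if cfg.two_step_correction:
                    confirm = _fdr_pass(p_hi, cfg.alpha) & (p_hi <= cfg.alpha / it)
                    reject = _fdr_pass(p_lo, cfg.alpha) & (p_lo <= cfg.alpha / it)
                else:
                    confirm = p_hi <= cfg.alpha / d
                    reject = p_lo <= cfg.alpha / d
                decision[und[confirm]] = CONFIRMED
                decision[und[reject & ~confirm]] = REJECTED
            if not (decision == UNDECIDED).any():
                break

        self.decision_ = decision
        self.hit_history_ = history
        self.hits_ = hits
        self.trials_ = trials
        self.n_iter_ = len(history)
        self.support_ = (decision == CONFIRMED) | (
            cfg.include_tentative & (decision == UNDECIDED)
        )
        self.n_features_in_ = d
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def run_boruta(
    matrix: ExpressionMatrix, labels: LabelVector, config: BorutaConfig | None = None
) -> BorutaResult:
    """Run shadow-feature selection on an ExpressionMatrix; returns the
    confirmed / rejected / tentative gene-id partition."""
    config = config or BorutaConfig()
    sel = BorutaSelector(
        max_iter=config.max_iter, alpha=config.alpha, n_trees=config.n_trees,
        two_step_correction=config.two_step_correction,
        include_tentative=config.include_tentative, random_state=config.seed,
    ).fit(matrix.values, labels.labels)
    genes = np.asarray(matrix.gene_ids, dtype=object)
    hist = {
        g: [bool(h[j]) for h in sel.hit_history_[: sel.trials_[j]]]
        for j, g in enumerate(genes)
    }
    return BorutaResult(
        confirmed=set(genes[sel.decision_ == CONFIRMED]),
        rejected=set(genes[sel.decision_ == REJECTED]),
        tentative=set(genes[sel.decision_ == UNDECIDED]),
        hit_history=hist,
    )
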