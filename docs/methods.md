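# Methods

## Problem setting

The package identifies marker genes for cell types in multi-class
expression data: given a non-negative cells × genes matrix and a cell-type
label per cell, it produces (i) a ranked gene list, (ii) an incremental
feature-selection (IFS) curve that locates the optimal and efficient panel
sizes, and (iii) a set of IF–THEN expression rules. Expression values are
treated as opaque non-negative reals — no normalization, QC or batch
handling is performed; callers feed the matrix in whatever units their
upstream processing produced.

## Stage models and parameters

### Mutual-information relevance filter

Continuous genes are discretized to three states around mean ± α·σ
(α = 1.0 by default; σ with denominator n, so a constant gene maps to all
"mid" and scores exactly zero). MI is the plug-in estimate from the joint
frequency table, in log base 2 (bits); zero-probability cells contribute
zero. The retention rule is strict: a gene survives iff MI > threshold,
default 0.001. Because the threshold's scale depends on the log base, both
the base (bits, fixed) and the threshold (configurable) are explicit;
0.001 bits is a permissive gate meant only to drop the clearly unrelated
tail. Note that plug-in MI has a positive finite-sample bias of roughly
(|X|−1)(|Y|−1)/(2·n·ln 2) bits, so on a few thousand cells most pure-noise
genes still score above 0.001 — the filter is intentionally the weakest
stage, and the shadow-feature stage does the real pruning.

### Shadow-feature (all-relevant) confirmation

Per iteration: every still-active gene is paired with a freshly permuted
shadow copy; a 100-tree random forest is fit on originals + shadows; a
gene scores a hit when its mean-decrease-in-impurity importance exceeds
the *maximum* shadow importance. Cumulative hits are tested against
Binomial(n_iter, ½). Two multiplicity modes:

* `two_step_correction=True` (default): a gene is decided only if it
  passes both a Benjamini–Hochberg step-up across the candidate genes at
  level α and a Bonferroni-across-iterations bound (p ≤ α / n_iter).
* `two_step_correction=False`: plain Bonferroni across genes
  (p ≤ α / d) each iteration.

Rejected genes leave the design matrix (shrinking the forest problem);
confirmed genes remain, keeping the importance competition honest. The
loop stops when no gene is undecided or at `max_iter` (default 100,
α = 0.05). Genes still undecided are *tentative* and are passed through to
the ranking stage by default — a ranking stage downstream can demote them,
whereas dropping them would be irreversible; `include_tentative=False`
drops them instead.

### Monte Carlo feature selection

Defaults: projection size m = ⌈0.05·d⌉ (≥ 1), number of projections
s = ⌈300·d/m⌉ capped at 20,000, and t = 5 stratified train/test resplits
(train fraction 0.66) per projection, so each feature is expected in about
300·t evaluated trees — enough for stable relative-importance (RI)
estimates at the scale this package targets, and all exposed in
`MCFSConfig`. Trees use the entropy criterion, making each split node's
impurity decrease a literal Shannon information gain in bits (verified
against scikit-learn's impurity accounting). wAcc is the unweighted mean
of per-class recall on the held-out split — balanced accuracy — so small
classes count equally. RI sums wAccᵘ · IG · (node fraction)ᵛ with
u = v = 1; node fraction is the node's training-sample share of the root.
Ranking ties are broken by input gene order, which keeps lists
reproducible. Degenerate resplits (single-class training side) are redrawn
up to 10 times, then the projection is skipped with a logged warning.

### SMOTE balancing

Minority classes are grown to the majority count with synthetic points
z = x + λ(y − x), λ ~ U(0,1), where y is one of x's k = 5 nearest
same-class neighbours (Euclidean distance on the current feature subset,
i.e. after IFS truncation). A class of size 1 is an error; k is clamped to
class size − 1 with a warning. Balancing happens **inside CV training
folds only**: synthetic points never reach a test fold, so reported MCCs
describe real cells. This in-fold placement is the only reading that
avoids leaking interpolated copies of test cells into training; a
`balance_before_cv` flag reproduces the leaky pre-CV variant for
comparison. The oversampler records each synthetic point's two parent
indices, which is what the convexity and provenance tests audit.

### Metrics

Multiclass MCC is computed from the N × K one-hot matrices of true and
predicted labels as cov(X,Y)/√(cov(X,X)·cov(Y,Y)) with per-class column
covariances summed; this equals Gorodkin's R_K and reduces to the
classical binary MCC at K = 2. Either variance term being zero (e.g. a
constant prediction) yields 0 by convention. Overall accuracy is the exact
match fraction; per-class accuracy is per-class recall. All metrics are
computed on pooled out-of-fold predictions (rather than averaged per
fold), which weights every cell once and is well-defined for classes
smaller than the fold count.

### Incremental feature selection

Prefix sizes run step, 2·step, … up to min(available, cap) with
step = 5 and cap = 1000; a non-multiple bound is appended as a final
partial prefix. Folds are stratified by per-class shuffled round-robin
assignment, which (unlike off-the-shelf stratified k-fold) accepts classes
smaller than the fold count — such classes simply occupy fewer folds.
The optimal k is the smallest prefix attaining the maximum MCC (ties break
toward fewer features); the efficient k is the smallest prefix with
MCC ≥ max − δ, δ = 0.02 by default — a formalization of the usual
by-eye knee-picking on IFS curves. Classifiers: a 100-tree random forest
and a single decision tree; the tree uses the entropy criterion so that
the IFS tree and the final rule-extraction tree are the same model family.

### Rule extraction

One entropy tree is fit on the full dataset restricted to the decision
tree's optimal prefix, by default on SMOTE-balanced data (so small cell
types get leaves at all); support and confidence are then counted on the
original cells only. Each leaf becomes a rule; the rule list is sorted by
support, then confidence, then extraction order, and the export is capped
at the top 1000. Because the rules partition the feature space, exactly
one rule fires per sample and the rule set reproduces the tree's
predictions exactly; the boundary convention (value ≤ θ goes left)
matches the tree's own split semantics. When trained on balanced data a
leaf may contain no original sample; such rules carry support 0 and sort
last.

## Synthetic study conditions

The generator emulates the properties that stress the pipeline — many
classes, heavy imbalance, few informative genes, sparse counts — without
claiming fidelity to any particular protocol. Defaults: 6 classes whose
sizes are drawn log-uniformly between 50 and 1000 cells (imbalance ratios
around one order of magnitude; the motivating atlases reach ratios of
several hundred), 500 genes of which 5 per class are markers, disjoint
across classes so recovery is unambiguous. Counts are negative binomial
with mean 1.0 and dispersion 0.5 (variance = μ + 0.5μ²); a marker's mean
inside its own class is multiplied by e^{effect_size} with
effect_size = 2.0; every value is then zeroed independently with
probability 0.3. One seed drives one named substream per operation, so
individual stages are reproducible in isolation.

What the generator does **not** model: overlapping marker programs,
hierarchical or correlated cell types, batch effects, library-size
variation, gene–gene correlation. Passing the recovery tests therefore
shows the chain is implemented correctly and has power under clean
planted signal — not that it will attain any particular MCC on real
atlases.

## Problem sizes and numerical choices

Tests and the acceptance script run the full chain on the default
conditions above (≈ 1,800 cells × 500 genes), the scale this package
treats as its reference experiment; the stage estimators themselves are
O(cells × genes) per tree and are routinely used on larger matrices
stage-by-stage via the CLI's resumable artifacts. Numerical conventions:
MI and IG in bits everywhere; MI symmetric and non-negative up to 1e−12;
RI aggregation is plain summation (tested against a straight-line
recomputation at 1e−12); MCC's zero-variance convention is 0; all
stochastic components (generator, shadows, forests, resplits, folds,
SMOTE) take explicit seeds, and the orchestrated pipeline derives one
fixed substream per stage from the global seed, making repeated runs
byte-identical.

## Known limitations

* The MI filter's 0.001 threshold is scale-dependent (bits here); users
  porting thresholds from nat-based tools should convert.
* Tentative shadow-feature genes are a judgment call; both forwarding
  (default) and dropping are supported.
* The IFS curve is recomputed per prefix from scratch; no warm-starting.
* Rule confidence is in-sample; no holdout calibration of rules.
* The pipeline assumes labels are trustworthy; label noise propagates
  into every stage.
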