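# Methods

## Pipeline overview

`svrules` turns a fitted kernel SVM into a compact ordered rule list in
five stages: fuzzy-weighted SVM fit → artificial dataset from the support
vectors → biased random forest (BRF) → rule harvesting → two-stage
reduction. Every stage is deterministic given its seed; the cross-
validation harness fans all seeds out from one master seed.

## Fuzzy SVM

The classifier solves the weighted soft-margin dual with RBF kernel
K(x, x′) = exp(−γ‖x−x′‖²) (so γ = 1/(2σ²)) and per-sample box constraints
0 ≤ α_i ≤ s_i·C. It is solved by libsvm (SMO) through scikit-learn's
`SVC` with `sample_weight = s`; the contract is dual optimality, not a
particular solver. With s ≡ 1 the fit is bit-identical to a standard SVM,
which the tests verify against a direct `SVC` fit and, on a four-point
problem, against a brute-force QP solution of the dual.

**Membership function.** The fuzzy weighting is the classic linear decay
with distance to the sample's class centroid,

    s_i = 1 − d_i / (d_max + δ),

with d_max the class's largest centroid distance and δ > 0 keeping the
farthest sample's weight positive. Default δ = 0.1·d_max per class; a
`crisp` mode (s ≡ 1) recovers the plain SVM. This is an interpretation:
the method family only prescribes *that* samples are fuzzy-weighted, not
the functional form, so the form is configurable. A class-balancing
variant (scaling majority weights by the class ratio) was evaluated during
development and discarded: it raised recall but cost more precision than
it gained, lowering MCC on the synthetic study data.

**Conventions.** External labels are {0, 1} with 1 the positive/minority
class; internally the dual uses ±1. A decision value of exactly zero maps
to the positive class (detection-oriented tie rule, used consistently
across the package). Support vectors are samples with α above
`sv_alpha_tolerance` (default 1e-8 — "strictly positive" is meaningless at
solver precision).

**Hyperparameters.** Default grids γ ∈ {0.1, 0.5, 1, 1.5, 2, 4} and
C ∈ {0.5, 1, 2, 4, 8, 16} are searched by validation-fold MCC, ties going
to smaller C then smaller γ (smoother models). On [0, 1]-scaled features
with a handful of dimensions the selected cells cluster around γ ≈ 1.5–4,
C ≈ 4–16.

## Artificial dataset

The support vectors with labels replaced by the fitted model's own
predictions. Replacing rather than keeping the labels is the point: margin
violators that the model (correctly) overrules carry their *predicted*
label into rule learning, which removes label noise. The SV class ratio is
reported in the training log — it is typically much less skewed than the
raw data, but the residual imbalance motivates the BRF.

## Biased random forest

Two sub-forests over the same feature space: `(1−p)·S` trees on bootstraps
of the full (artificial) dataset and `p·S` trees on bootstraps of the
critical set — all minority samples plus the union of each one's k nearest
majority neighbors (Euclidean distance on the scaled features, duplicates
collapsed; k saturates at the majority size). Prediction is an unweighted
majority vote, ties to the positive class. Defaults: S = 100 trees,
p = 0.5, k = 10, Gini splitting, ⌈√d⌉ candidate features per split.

As a standalone classifier `BrfConfig` defaults to depth-6 trees. Inside
the rule-extraction pipeline the default depth is 2: candidate rules then
carry at most two conditions, which matches the short screening rules the
method is meant to produce, and measurably improves held-out performance
of the reduced list (deep paths memorize residual noise that the reduction
stage must then discard). Depth-2 trees are individually weak — the raw
forest vote is *not* the deliverable; the reduced list is.

The critical set must contain both classes, otherwise fitting aborts. The
minority class is the less frequent label (ties resolve to the positive
class); on the pipeline's artificial datasets this is usually still the
positive class.

## Rule harvesting

Left branches contribute `feature ≤ threshold`, right branches the strict
complement, the leaf's predicted class labels the rule — so a tree's rules
partition feature space and the ruleset reproduces the forest vote
exactly. Rule matching casts query features to float32 first, the same
representation the trees predict on, making the equivalence bit-exact.
Repeated splits on one feature are merged to the tightest interval
(minimum of upper bounds, maximum of lower bounds), which provably leaves
the covered set unchanged.

Per-rule statistics (error rate = misjudged covered / covered, coverage =
covered / N) are computed on the original training data by default; a
configuration switch (`rule_stats_on="artificial"`) scores them on the
artificial dataset instead. Scoring on the training data re-anchors the
candidate rules to the true labels, which is why the reduced list can beat
the SVM whose behaviour seeded it. A rule covering zero samples has error
1.0 by convention, so it can never win a selection round.

## Reduction

**Stage 1 — condition pruning.** Conditions are revisited in root-to-leaf
order; condition j is dropped when

    D_j = (err_−j − err_0) / max(err_0, s) < 0.05,

updating err_0 := err_−j after each removal. The stabilizer s (default
0.01) bounds D_j when err_0 ≈ 0. Single pass by default; a `fixpoint` mode
repeats until stable. Removing a conjunct can only widen the covered set,
so coverage is non-decreasing across pruning. Pruning can strip a rule
down to an empty conjunction; such rules are excluded from the selection
pool because the adaptive default rule subsumes them (an unflagged
match-everything rule would otherwise shadow the default — this was an
observed failure mode, not a theoretical one).

**Stage 2 — coverage filter and greedy selection.** Rules with training
coverage below g are discarded and a default rule (empty conditions,
training-majority label L*) is appended. Selection then loops: every
remaining rule's error rate is recomputed on the remaining training
samples; the minimizer is appended; the samples it covers are removed; L*
is updated to the majority of what is left (ties to positive). The loop
stops when the default wins a round (it is appended with its current L*)
or the training set is exhausted (the default is appended with its
original label). Ties on error are broken by higher remaining coverage,
then fewer conditions, then pool order; a stored rule wins an exact tie
against the default — otherwise the exhausted-training-set branch could
never trigger, since a full-coverage rule's error is never strictly below
the default's. Duplicate rules collapse before selection. Prediction is
first-match-wins and total by construction.

**The coverage threshold g** defaults to 0.15: each surviving candidate
must describe at least 15% of the training cohort. The value was
calibrated once on development simulations (planted-rule data, seeds
disjoint from those used anywhere in the test suite): at g ≈ 0.01 the
greedy stage assembles ~180-rule lists dominated by tiny zero-error rules
that memorize label noise; between 0.1 and 0.2 the lists plateau at
around a dozen rules with materially better held-out MCC. g is a visible
knob on the CLI and in the config file.

## Evaluation

Positive-class precision/recall/F1, accuracy, and MCC

    MCC = (TP·TN − FP·FN) / √((TP+FN)(TN+FP)(TP+FP)(TN+FN)),

with conventions: empty precision/recall denominators give 0, and a zero
factor in the MCC radicand gives 0. MCC is the headline metric because it
remains informative under imbalance. Rule counts include the default rule.

The CV harness splits into five stratified folds; per round fold t is the
test set, fold t+1 the validation set, the rest training. The min–max
scaler is fitted on the data the model is fitted on (training folds for
the grid search, train+validation for the final fit) and reused on the
held-out fold; out-of-range values clip to [0, 1]; constant features map
to 0.

## Synthetic data

`generate_planted` draws features uniformly on [0, 1]^d, labels a sample
positive iff it falls in any of the planted axis-aligned boxes, flips
labels independently with probability `noise_rate`, and collects exact
class counts for the requested negative:positive ratio by rejection from
the i.i.d. stream (equivalent to majority subsampling — the planted
geometry is untouched). Defaults emulate an imbalanced screening cohort:
n = 3000, d = 6, two positive boxes covering ≈ 20% of the cube, 5% label
noise, ratio 1:6 — within the 1:1.87–1:11.2 range of published diabetes
cohorts. What it does *not* emulate: correlated clinical covariates,
mixed continuous/ordinal scales, measurement error structure, or
prevalence drift; passing tests therefore demonstrate correct mechanics
and recovery of axis-aligned structure, not clinical performance.

With 5% noise and 1:6 imbalance the Bayes-optimal predictor (the planted
boxes themselves) attains MCC ≈ 0.83–0.87 on held-out draws; the
pipeline's reduced lists typically reach 0.80–0.87 with 8–14 rules,
i.e. close to the ceiling. Held-out performance in the end-to-end tests is
measured on an independently generated 3000-sample draw rather than a
600-sample fold, because the fold-level MCC estimate carries sampling
noise of the same order as the margin being tested.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at the
study scale (n = 3000, five folds / ten seeds); a pipeline fit takes a few
seconds on one core. Gaussian-cluster fixtures (n ≈ 200–300) cover the
unit-level contracts. All stochastic components take explicit integer
seeds; `numpy.random.SeedSequence` derives stage seeds from the master
seed, so every reported number is reproducible bit-for-bit.

## Known limitations

- The membership function and the BRF voting scheme (equal weights) are
  interpretations of an under-specified method family; both are
  configurable where alternatives are plausible.
- Greedy selection has no global-optimality guarantee; it inherits the
  usual sequential-covering failure mode of order-dependent rule overlap.
- No missing-data handling, categorical encoding, multiclass support, or
  kernels other than RBF.
- Feature selection guarantees ordering semantics only; the absolute scale
  of forest importances depends on the forest configuration.
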