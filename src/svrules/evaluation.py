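"""Confusion-matrix metrics and the fivefold cross-validation harness.

Scores are reported for the positive (minority) class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

MCC is the headline number because it stays informative under class
imbalance.  Zero-denominator conventions: precision/recall with an empty
denominator are 0, F1 with precision + recall = 0 is 0, and MCC is 0 when
any factor of the radicand vanishes.

The CV harness mirrors the intended study design: five stratified folds;
per round one fold is the test set, one the validation set and three the
training set.  The scaler is fitted on training data only, hyperparameters
are grid-searched on the validation fold, the SVM is refitted on
train+validation, and the full extract-and-reduce pipeline is scored on the
untouched test fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from svrules.brf import BrfConfig, brf_predict, fit_brf
from svrules.fuzzy_svm import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    SvmConfig,
    build_artificial_dataset,
    compute_membership,
    fit_fuzzy_svm,
    grid_search_svm,
    svm_predict,
)
from svrules.rule_extraction import extract_initial_ruleset, ruleset_predict
from svrules.rule_reduction import (
    PruneConfig,
    decision_list_predict,
    reduce_ruleset,
)
from svrules.tabular_io import (
    Dataset,
    apply_minmax,
    concat_datasets,
    fit_minmax,
    stratified_5fold,
)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    rule_count: int | None = None


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Counts with class 1 as positive."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(cm: ConfusionMatrix, rule_count: int | None = None) -> Metrics:
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    accuracy = (tp + tn) / cm.total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    radicand = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(radicand) if radicand else 0.0
    return Metrics(accuracy=accuracy, precision=precision, recall=recall,
                   f1=f1, mcc=mcc, rule_count=rule_count)


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end pipeline in one document.

    The BRF default here uses two-level trees: candidate rules then carry at
    most two conditions, matching the short clinical screening rules the
    method aims for; deeper trees produce longer rules that the reduction
    stage must work harder to discard.  The coverage threshold ``g`` was
    calibrated once on development simulations (planted-rule data) so that
    surviving rules describe clinically meaningful fractions of a cohort.
    """

    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    C_grid: tuple = DEFAULT_C_GRID
    sv_alpha_tolerance: float = 1e-8
    membership_mode: str = "centroid"
    membership_delta: float | None = None
    brf: BrfConfig = field(default_factory=lambda: BrfConfig(max_depth=2))
    prune: PruneConfig = field(default_factory=PruneConfig)
    g: float = 0.15
    rule_stats_on: str = "training"  # or "artificial"

    def __post_init__(self):
        if self.rule_stats_on not in ("training", "artificial"):
            raise ValueError("rule_stats_on must be 'training' or 'artificial'")


@dataclass
class PipelineResult:
    scaler: object
    svm_config: SvmConfig
    svm_model: object
    artificial: Dataset
    brf_model: object
    initial_ruleset: object
    decision_list: object
    metrics: dict[str, Metrics] | None = None


def run_pipeline(train: Dataset, valid: Dataset, test: Dataset | None,
                 config: PipelineConfig, seed: int = 0) -> PipelineResult:
    """Fit the whole chain on train(+valid) and optionally score on test.

    Steps: min-max scaling (fitted on the data the model is fitted on), grid
    search of (gamma, C) on the validation fold, fuzzy-SVM refit on
    train+validation, artificial dataset from the SVs, BRF on the artificial
    dataset, rule harvesting (statistics on the training data by default),
    and two-stage reduction to a decision list.
    """
    scaler0 = fit_minmax(train)
    svm_config = grid_search_svm(
        apply_minmax(scaler0, train), apply_minmax(scaler0, valid),
        gamma_grid=config.gamma_grid, C_grid=config.C_grid,
        membership_mode=config.membership_mode,
        membership_delta=config.membership_delta,
        sv_alpha_tolerance=config.sv_alpha_tolerance)

    trainval = concat_datasets(train, valid)
    scaler = fit_minmax(trainval)
    fit_data = apply_minmax(scaler, trainval)
    membership = compute_membership(fit_data, delta=config.membership_delta,
                                    mode=config.membership_mode)
    svm_model = fit_fuzzy_svm(fit_data, membership, svm_config)
    artificial = build_artificial_dataset(svm_model)

    brf_config = BrfConfig(**{**config.brf.__dict__, "seed": seed})
    brf_model = fit_brf(artificial, brf_config)

    stats_data = fit_data if config.rule_stats_on == "training" else artificial
    initial = extract_initial_ruleset(brf_model, stats_data)
    dlist = reduce_ruleset(initial, stats_data, config.prune, config.g)

    metrics = None
    if test is not None:
        test_n = apply_minmax(scaler, test)
        metrics = {
            "svm": compute_metrics(
                confusion(test_n.y, svm_predict(svm_model, test_n.X))),
            "initial": compute_metrics(
                confusion(test_n.y, ruleset_predict(initial, test_n.X)),
                rule_count=len(initial)),
            "reduced": compute_metrics(
                confusion(test_n.y, decision_list_predict(dlist, test_n.X)),
                rule_count=len(dlist)),
        }
    return PipelineResult(scaler=scaler, svm_config=svm_config,
                          svm_model=svm_model, artificial=artificial,
                          brf_model=brf_model, initial_ruleset=initial,
                          decision_list=dlist, metrics=metrics)


STAGES = ("svm", "initial", "reduced")


@dataclass
class CvResult:
    """Per-fold metrics per stage plus mean/sd summaries."""

    fold_metrics: list[dict[str, Metrics]]
    seed: int

    def stage_values(self, stage: str, attr: str) -> np.ndarray:
        return np.array([getattr(m[stage], attr) for m in self.fold_metrics],
                        dtype=float)

    def mean_sd(self, stage: str, attr: str) -> tuple[float, float]:
        vals = self.stage_values(stage, attr)
        return float(vals.mean()), float(vals.std(ddof=1))

    def summary_rows(self):
        rows = []
        for stage in STAGES:
            row = {"stage": stage}
            for attr in ("accuracy", "precision", "recall", "f1", "mcc"):
                mean, sd = self.mean_sd(stage, attr)
                row[attr] = mean
                row[f"{attr}_sd"] = sd
            if stage != "svm":
                mean, sd = self.mean_sd(stage, "rule_count")
                row["rules"] = mean
                row["rules_sd"] = sd
            rows.append(row)
        return rows


def run_cv(dataset: Dataset, config: PipelineConfig | None = None,
           seed: int = 0) -> CvResult:
    """Fivefold CV of the full pipeline; deterministic for a fixed seed.

    Fold t is the test set, fold (t+1) mod 5 the validation set, the
    remaining three folds the training set.  All downstream seeds fan out
    from the master seed.
    """
    config = config or PipelineConfig()
    plan = stratified_5fold(dataset, seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(5) % (2**31 - 1)
    fold_metrics = []
    for t in range(plan.N_FOLDS):
        v = (t + 1) % plan.N_FOLDS
        test = dataset.subset(plan.fold_indices(t))
        valid = dataset.subset(plan.fold_indices(v))
        train = dataset.subset(plan.complement_indices(t, v))
        result = run_pipeline(train, valid, test, config,
                              seed=int(child_seeds[t]))
        fold_metrics.append(result.metrics)
    return CvResult(fold_metrics=fold_metrics, seed=seed)
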