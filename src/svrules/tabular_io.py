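"""Tabular dataset container, delimited-text I/O, scaling and fold splitting.

The pipeline's universal currency is a :class:`Dataset`: a numeric feature
matrix, a binary label vector (1 = positive / minority class, e.g. diabetic)
and ordered feature names.  Files are plain delimited text with a mandatory
header; missing values and labels outside {0, 1} are rejected rather than
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold


@dataclass
class Dataset:
    """Feature matrix ``X`` (n x d), binary labels ``y`` and feature names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        self.y = np.asarray(self.y, dtype=np.int64).ravel()
        self.feature_names = list(self.feature_names)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X has {self.X.shape[1]} columns but "
                f"{len(self.feature_names)} feature names were given"
            )
        bad = set(np.unique(self.y)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        pos = int(self.y.sum())
        return self.n_samples - pos, pos

    def imbalance_ratio(self) -> float:
        """Negative-to-positive ratio (inf when no positives)."""
        neg, pos = self.class_counts()
        return np.inf if pos == 0 else neg / pos

    def subset(self, indices) -> "Dataset":
        idx = np.asarray(indices)
        return Dataset(self.X[idx], self.y[idx], self.feature_names)


def concat_datasets(a: Dataset, b: Dataset) -> Dataset:
    if a.feature_names != b.feature_names:
        raise ValueError("feature names differ between datasets")
    return Dataset(np.vstack([a.X, b.X]), np.concatenate([a.y, b.y]), a.feature_names)


def load_dataset(path, label_column: str, sep: str = ",") -> Dataset:
    """Read a delimited text file with a header row into a :class:`Dataset`.

    Every non-label column must parse as a number; the label column must hold
    only 0 and 1.  Offending cells are reported by row (0-based data row) and
    column name.
    """
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    feature_cols = [c for c in frame.columns if c != label_column]
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"non-numeric or missing value in column {col!r}, row {bad[0]}"
            )
        frame[col] = vals
    labels = frame[label_column].to_numpy()
    outside = np.nonzero(~np.isin(labels, (0, 1)))[0]
    if outside.size:
        raise ValueError(
            f"label value {labels[outside[0]]!r} outside {{0, 1}} in column "
            f"{label_column!r}, row {outside[0]}"
        )
    X = frame[feature_cols].to_numpy(dtype=np.float64)
    return Dataset(X, labels.astype(np.int64), feature_cols)


def save_dataset(dataset: Dataset, path, label_column: str = "label",
                 sep: str = ",") -> None:
    """Write a dataset as delimited text (full float precision, round-trip safe)."""
    frame = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    frame[label_column] = dataset.y
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass
class MinMaxScaler:
    """Per-feature [min, max] observed on a fitting set, mapping onto [0, 1].

    Values outside the fitted range transform to clipped 0/1; a constant
    feature (min == max) maps to 0 everywhere, carrying no information.
    """

    min_: np.ndarray
    max_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        span = self.max_ - self.min_
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = (X[:, nz] - self.min_[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0)

    def inverse_transform_thresholds(self, feature_index: int,
                                     value: float) -> float:
        """Map a normalized threshold back to the original feature scale."""
        lo, hi = self.min_[feature_index], self.max_[feature_index]
        return float(lo + value * (hi - lo))


def fit_minmax(train: Dataset) -> MinMaxScaler:
    if train.n_samples == 0:
        raise ValueError("cannot fit a scaler on an empty dataset")
    return MinMaxScaler(train.X.min(axis=0), train.X.max(axis=0))


def apply_minmax(scaler: MinMaxScaler, data: Dataset) -> Dataset:
    return Dataset(scaler.transform(data.X), data.y, data.feature_names)


@dataclass
class FoldPlan:
    """Stratified fivefold assignment: per-sample fold index in 0..4."""

    seed: int
    assignments: np.ndarray = field(repr=False)

    N_FOLDS = 5

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def complement_indices(self, *folds: int) -> np.ndarray:
        return np.nonzero(~np.isin(self.assignments, folds))[0]


def stratified_5fold(dataset: Dataset, seed: int) -> FoldPlan:
    """Partition samples into five label-stratified, near-equal folds.

    Deterministic for a fixed seed; each class must contribute at least five
    samples so that every fold sees both classes.
    """
    neg, pos = dataset.class_counts()
    if min(neg, pos) < FoldPlan.N_FOLDS:
        raise ValueError(
            f"each class needs >= {FoldPlan.N_FOLDS} samples for stratified "
            f"fivefold splitting (got {neg} negatives, {pos} positives)"
        )
    skf = StratifiedKFold(n_splits=FoldPlan.N_FOLDS, shuffle=True,
                          random_state=seed)
    assignments = np.empty(dataset.n_samples, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(dataset.X, dataset.y)):
        assignments[test_idx] = fold
    return FoldPlan(seed=seed, assignments=assignments)


# --- rule interchange -------------------------------------------------------

RULE_FORMAT_VERSION = 1


def save_rules(rules, path, feature_names=None, scaler: MinMaxScaler | None = None,
               extra: dict | None = None) -> None:
    """Write rules as versioned JSON interchange (one record per rule).

    When a fitted scaler is supplied, each condition additionally carries the
    threshold mapped back to the original feature scale.
    """
    import json

    records = []
    for rule in rules:
        conds = []
        for c in rule.conditions:
            rec = {"feature": int(c.feature), "op": c.op,
                   "threshold": float(c.threshold)}
            if feature_names is not None:
                rec["feature_name"] = feature_names[c.feature]
            if scaler is not None:
                rec["threshold_original"] = scaler.inverse_transform_thresholds(
                    c.feature, c.threshold)
            conds.append(rec)
        records.append({
            "conditions": conds,
            "label": int(rule.label),
            "error_rate": None if rule.err is None else float(rule.err),
            "coverage": None if rule.coverage is None else float(rule.coverage),
            "selection_order": rule.selection_order,
            "is_default": bool(rule.is_default),
        })
    doc = {"format_version": RULE_FORMAT_VERSION, "rules": records}
    if feature_names is not None:
        doc["feature_names"] = list(feature_names)
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_rules(path):
    """Read rules from the JSON interchange format."""
    import json

    from svrules.rule_extraction import Condition, Rule

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != RULE_FORMAT_VERSION:
        raise ValueError(f"unsupported rule format version {doc.get('format_version')}")
    rules = []
    for rec in doc["rules"]:
        conds = tuple(Condition(c["feature"], c["op"], c["threshold"])
                      for c in rec["conditions"])
        rules.append(Rule(conditions=conds, label=rec["label"],
                          err=rec.get("error_rate"),
                          coverage=rec.get("coverage"),
                          selection_order=rec.get("selection_order"),
                          is_default=rec.get("is_default", False)))
    return rules, doc.get("feature_names")


def format_rule(rule, feature_names=None) -> str:
    """Human-readable one-line rendering, e.g. ``IF age > 0.43 AND tg <= 0.21 THEN 1``."""
    if rule.conditions:
        parts = []
        for c in rule.conditions:
            name = feature_names[c.feature] if feature_names else f"x{c.feature}"
            parts.append(f"{name} {c.op} {c.threshold:.6g}")
        body = "IF " + " AND ".join(parts)
    else:
        body = "DEFAULT"
    stats = ""
    if rule.err is not None or rule.coverage is not None:
        err = "?" if rule.err is None else f"{rule.err:.4f}"
        cov = "?" if rule.coverage is None else f"{rule.coverage:.4f}"
        stats = f" [err={err}, cov={cov}]"
    return f"{body} THEN {rule.label}{stats}"
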