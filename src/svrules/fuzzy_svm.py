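"""Fuzzy-membership-weighted soft-margin RBF SVM and the artificial dataset.

The classifier solves the weighted soft-margin dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= s_i * C,   sum_i a_i y_i = 0

with the RBF kernel K(x, x') = exp(-gamma * ||x - x'||^2) and per-sample
membership weights s_i in (0, 1] that de-emphasize outliers (weighted-penalty
fuzzy SVM).  With all s_i = 1 this is exactly the standard soft-margin SVM.
Labels are coded +/-1 internally; the external convention stays {0, 1} with
1 the positive/minority class, and a decision value of exactly zero maps to
the positive class.

Support vectors (SVs) are the training samples with dual coefficient above a
small tolerance; the decision function depends on them alone.  The
"artificial dataset" for downstream rule extraction consists of the SVs with
their labels *replaced* by the fitted model's own predictions, which removes
label noise from the rule-learning target.

The dual is solved by libsvm via scikit-learn; the contract is optimality of
the dual objective, not a particular solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from svrules.tabular_io import Dataset

#: hyperparameter grids for tuning; they bracket the (gamma=1.5, C=4)
#: region that works well on [0,1]-scaled clinical data
DEFAULT_GAMMA_GRID = (0.1, 0.5, 1.0, 1.5, 2.0, 4.0)
DEFAULT_C_GRID = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass
class SvmConfig:
    """RBF-SVM hyperparameters.

    ``gamma`` parameterizes the kernel as exp(-gamma * ||x - x'||^2), i.e.
    gamma = 1 / (2 sigma^2) in the bandwidth form.  ``sv_alpha_tolerance``
    is the numeric cutoff standing in for "alpha strictly positive".
    """

    C: float = 4.0
    gamma: float = 1.5
    sv_alpha_tolerance: float = 1e-8

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.sv_alpha_tolerance < 0:
            raise ValueError("sv_alpha_tolerance must be >= 0")


@dataclass
class SvmModel:
    """Fitted weighted kernel machine: SVs, signed dual coefficients, bias."""

    sv_X: np.ndarray
    sv_signed_alpha: np.ndarray  # alpha_i * y_i with y in {-1, +1}
    sv_labels: np.ndarray        # original {0, 1} labels of the SVs
    intercept: float
    config: SvmConfig
    feature_names: list[str]
    support_indices: np.ndarray
    alpha_full: np.ndarray = field(repr=False)  # alpha over all training samples
    fit_X: np.ndarray = field(repr=False)       # training features (diagnostics)
    fit_y_signed: np.ndarray = field(repr=False)

    @property
    def n_support(self) -> int:
        return self.sv_X.shape[0]

    def sv_class_ratio(self) -> float:
        """Negative:positive ratio among the SVs' original labels."""
        pos = int(self.sv_labels.sum())
        return np.inf if pos == 0 else (self.sv_labels.size - pos) / pos


def compute_membership(dataset: Dataset, delta: float | None = None,
                       mode: str = "centroid") -> np.ndarray:
    """Per-sample fuzzy membership weights s_i in (0, 1].

    ``centroid`` mode uses the classic linear decay with distance to the
    sample's class centroid: s_i = 1 - d_i / (d_max + delta), where d_max is
    the class's largest centroid distance and delta > 0 keeps the farthest
    sample's weight positive (default delta = 0.1 * d_max per class).
    ``crisp`` mode returns all ones, recovering the standard SVM.
    """
    if mode == "crisp":
        return np.ones(dataset.n_samples)
    if mode != "centroid":
        raise ValueError(f"unknown membership mode {mode!r}")
    weights = np.ones(dataset.n_samples)
    for label in (0, 1):
        idx = np.nonzero(dataset.y == label)[0]
        if idx.size <= 1:
            continue
        Xc = dataset.X[idx]
        dist = np.linalg.norm(Xc - Xc.mean(axis=0), axis=1)
        d_max = dist.max()
        if d_max == 0:
            continue
        dlt = 0.1 * d_max if delta is None else delta
        weights[idx] = 1.0 - dist / (d_max + dlt)
    return weights


def fit_fuzzy_svm(dataset: Dataset, membership: np.ndarray,
                  config: SvmConfig) -> SvmModel:
    """Solve the membership-weighted dual; returns the model with its SVs.

    The per-sample penalty cap is s_i * C (sample weights scale the box
    constraint).  Raises if the solver does not converge within its
    iteration budget or if only one class is present.
    """
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("both classes must be present to fit an SVM")
    membership = np.asarray(membership, dtype=np.float64)
    if membership.shape != (dataset.n_samples,):
        raise ValueError("membership length must match the number of samples")
    if np.any(membership <= 0) or np.any(membership > 1):
        raise ValueError("membership weights must lie in (0, 1]")

    svc = SVC(C=config.C, kernel="rbf", gamma=config.gamma, max_iter=200_000)
    svc.fit(dataset.X, dataset.y, sample_weight=membership)
    if svc.fit_status_ != 0:
        raise RuntimeError("SVM solver did not converge within the iteration budget")

    n = dataset.n_samples
    signed_full = np.zeros(n)
    signed_full[svc.support_] = svc.dual_coef_[0]  # alpha_i * y_i, y(class 1) = +1
    alpha_full = np.abs(signed_full)

    keep = alpha_full[svc.support_] > config.sv_alpha_tolerance
    support = svc.support_[keep]
    assert support.size > 0, "a fitted SVM must retain at least one SV"
    return SvmModel(
        sv_X=dataset.X[support].copy(),
        sv_signed_alpha=signed_full[support].copy(),
        sv_labels=dataset.y[support].copy(),
        intercept=float(svc.intercept_[0]),
        config=config,
        feature_names=list(dataset.feature_names),
        support_indices=support,
        alpha_full=alpha_full,
        fit_X=dataset.X,
        fit_y_signed=np.where(dataset.y == 1, 1.0, -1.0),
    )


def _rbf(gamma: float, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.exp(-gamma * cdist(np.atleast_2d(A), np.atleast_2d(B),
                                 "sqeuclidean"))


def decision_function(model: SvmModel, X, use_full_alpha: bool = False
                      ) -> np.ndarray:
    """f(x) = sum_i alpha_i y_i K(x_i, x) + b.

    By default only the stored SVs enter the sum; ``use_full_alpha``
    evaluates over every training sample instead (non-SVs contribute zero),
    which is useful for verifying SV sufficiency.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.sv_X.shape[1]:
        raise ValueError(
            f"query has {X.shape[1]} features, model expects {model.sv_X.shape[1]}")
    if use_full_alpha:
        coef = model.alpha_full * model.fit_y_signed
        K = _rbf(model.config.gamma, X, model.fit_X)
    else:
        coef = model.sv_signed_alpha
        K = _rbf(model.config.gamma, X, model.sv_X)
    return K @ coef + model.intercept


def svm_predict(model: SvmModel, X) -> np.ndarray:
    """{0,1} labels; a decision value of exactly 0 maps to the positive class."""
    return (decision_function(model, X) >= 0).astype(np.int64)


def build_artificial_dataset(model: SvmModel) -> Dataset:
    """SVs with labels replaced by the model's own predictions.

    The original labels of the SVs are discarded; relabelling by the fitted
    machine is what removes label noise before rule extraction.
    """
    return Dataset(model.sv_X.copy(), svm_predict(model, model.sv_X),
                   model.feature_names)


def grid_search_svm(train: Dataset, valid: Dataset,
                    gamma_grid=DEFAULT_GAMMA_GRID, C_grid=DEFAULT_C_GRID,
                    membership_mode: str = "centroid",
                    membership_delta: float | None = None,
                    sv_alpha_tolerance: float = 1e-8) -> SvmConfig:
    """Pick the (gamma, C) cell with the best validation MCC.

    Ties are broken toward smaller C, then smaller gamma (simpler, smoother
    models).
    """
    from svrules.evaluation import compute_metrics, confusion

    if not gamma_grid or not C_grid:
        raise ValueError("grids must be non-empty")
    membership = compute_membership(train, delta=membership_delta,
                                    mode=membership_mode)
    best: tuple[float, SvmConfig] | None = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            cfg = SvmConfig(C=C, gamma=gamma,
                            sv_alpha_tolerance=sv_alpha_tolerance)
            model = fit_fuzzy_svm(train, membership, cfg)
            mcc = compute_metrics(
                confusion(valid.y, svm_predict(model, valid.X))).mcc
            if best is None or mcc > best[0]:
                best = (mcc, cfg)
    return best[1]
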