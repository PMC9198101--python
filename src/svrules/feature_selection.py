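"""Filter + embedded feature ranking: chi-square, information gain, forest Gini.

Continuous features are discretized by equal-frequency binning (robust to
skewed clinical measurements) before the chi-square test and information
gain; Gini importance comes from a standard (unbiased, full-data) random
forest.  Features are ranked 1..d under each criterion (ties share the mean
rank), averaged, and the top-k by best (smallest) average rank are selected
after discarding features whose chi-square p-value fails significance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from svrules.tabular_io import Dataset

DEFAULT_N_BINS = 10
DEFAULT_P_THRESHOLD = 0.05


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Integer bin codes from equal-frequency (quantile) edges.

    A constant feature collapses to a single bin.  Values equal to an edge
    fall in the lower bin, so codes depend only on the ordering of the data —
    monotone rescaling leaves them unchanged.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(x, qs))
    return np.searchsorted(edges, x, side="left")


def chi_square_scores(dataset: Dataset, n_bins: int = DEFAULT_N_BINS
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-square of binned-feature x label tables; returns (stat, p).

    Empty bins are dropped from the table.  A single-bin (constant) feature
    scores 0 with p-value 1.
    """
    stats_, pvals = np.empty(dataset.n_features), np.empty(dataset.n_features)
    y = dataset.y
    for j in range(dataset.n_features):
        codes = equal_frequency_bins(dataset.X[:, j], n_bins)
        table = pd.crosstab(codes, y).to_numpy()
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            stats_[j], pvals[j] = 0.0, 1.0
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        stats_[j], pvals[j] = chi2, p
    return stats_, pvals


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain_scores(dataset: Dataset, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Information gain H(label) - H(label | binned feature), in bits."""
    y = dataset.y
    h_y = _entropy_bits(np.bincount(y))
    gains = np.empty(dataset.n_features)
    for j in range(dataset.n_features):
        codes = equal_frequency_bins(dataset.X[:, j], n_bins)
        h_cond = 0.0
        for code in np.unique(codes):
            sel = codes == code
            h_cond += sel.mean() * _entropy_bits(np.bincount(y[sel]))
        gains[j] = h_y - h_cond
    return gains


def gini_importance(dataset: Dataset, n_estimators: int = 200,
                    seed: int = 0, **forest_kwargs) -> np.ndarray:
    """Mean Gini impurity-decrease importance from a standard random forest.

    Importances are normalized to sum to 1 (scikit-learn convention).
    """
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("Gini importance needs both classes present")
    forest = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=seed, **forest_kwargs)
    forest.fit(dataset.X, dataset.y)
    return forest.feature_importances_


def rank_features(dataset: Dataset, n_bins: int = DEFAULT_N_BINS,
                  n_estimators: int = 200, seed: int = 0) -> pd.DataFrame:
    """Per-feature scores, per-criterion ranks (1 = best) and average rank.

    Returns a DataFrame indexed by feature name with columns ``chi2``,
    ``chi2_p``, ``info_gain``, ``gini``, the three ``*_rank`` columns and
    ``average_rank`` (arithmetic mean of the three ranks; ties within a
    criterion share the mean rank).
    """
    chi2, pvals = chi_square_scores(dataset, n_bins)
    gains = info_gain_scores(dataset, n_bins)
    gini = gini_importance(dataset, n_estimators=n_estimators, seed=seed)
    frame = pd.DataFrame({
        "chi2": chi2, "chi2_p": pvals, "info_gain": gains, "gini": gini,
    }, index=pd.Index(dataset.feature_names, name="feature"))
    for col in ("chi2", "info_gain", "gini"):
        frame[f"{col}_rank"] = stats.rankdata(-frame[col], method="average")
    frame["average_rank"] = frame[
        ["chi2_rank", "info_gain_rank", "gini_rank"]].mean(axis=1)
    return frame


def average_rank_select(ranking: pd.DataFrame, top_k: int,
                        p_threshold: float = DEFAULT_P_THRESHOLD) -> list[str]:
    """Top-k features by best average rank among the chi-square-significant ones.

    Features with chi-square p-value >= ``p_threshold`` are excluded before
    truncation, regardless of rank.  Ties on average rank are broken by the
    chi-square rank, then by original feature order.  If fewer than ``top_k``
    features survive the significance filter, all survivors are returned with
    a warning.
    """
    if top_k > len(ranking):
        raise ValueError("top_k exceeds the number of ranked features")
    significant = ranking[ranking["chi2_p"] < p_threshold].copy()
    significant["_order"] = np.arange(len(significant))
    significant = significant.sort_values(
        ["average_rank", "chi2_rank", "_order"], kind="stable")
    if len(significant) < top_k:
        warnings.warn(
            f"only {len(significant)} of {len(ranking)} features are "
            f"significant at p < {p_threshold}; returning all of them",
            stacklevel=2)
    return list(significant.index[:top_k])
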