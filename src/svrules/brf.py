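"""Biased random forest (BRF) for imbalanced binary data.

A BRF combines two sub-forests over the same feature space: one grown on
bootstraps of the full dataset and one grown on bootstraps of the *critical
set* — every minority-class sample together with its k nearest majority
neighbors (Euclidean distance on the [0,1]-scaled features, duplicates
collapsed).  Concentrating part of the ensemble on the neighborhood of the
minority class moves the usual resampling correction from the data level to
the model level: the critical trees see a far more balanced problem, which
raises minority recall without discarding majority structure.

Prediction is an unweighted majority vote over all trees, with ties going to
the positive class (the pipeline's detection-oriented convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from svrules.tabular_io import Dataset

FULL, CRITICAL = "full", "critical"


@dataclass
class BrfConfig:
    """Ensemble shape: total trees S, critical fraction p, k-NN size, tree depth.

    ``bias_ratio`` p is the fraction of trees grown on the critical set
    (round(p*S) trees); p=0 reduces to a plain random forest.  Shallow trees
    (``max_depth`` 6 by default) keep the harvested rules short.
    """

    n_trees: int = 100
    bias_ratio: float = 0.5
    k: int = 10
    max_depth: int | None = 6
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")
        if not 0 <= self.bias_ratio <= 1:
            raise ValueError("bias_ratio must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def n_critical_trees(self) -> int:
        return int(round(self.bias_ratio * self.n_trees))

    @property
    def n_full_trees(self) -> int:
        return self.n_trees - self.n_critical_trees


@dataclass
class BrfModel:
    """Fitted ensemble: trees tagged 'full' or 'critical', plus metadata."""

    trees: list = field(repr=False)
    tags: list[str]
    config: BrfConfig
    critical_indices: np.ndarray
    feature_names: list[str]

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def find_critical_set(dataset: Dataset, k: int) -> np.ndarray:
    """Minority samples plus the union of their k nearest majority neighbors.

    The minority class is the less frequent label (ties resolve to the
    positive class).  k saturates at the majority size, in which case the
    critical set is the whole dataset.  Returns sorted unique indices.
    """
    neg, pos = dataset.class_counts()
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present to build a critical set")
    minority_label = 1 if pos <= neg else 0
    minority = np.nonzero(dataset.y == minority_label)[0]
    majority = np.nonzero(dataset.y != minority_label)[0]
    k_eff = min(k, majority.size)
    nn = NearestNeighbors(n_neighbors=k_eff)
    nn.fit(dataset.X[majority])
    neighbor_rows = nn.kneighbors(dataset.X[minority], return_distance=False)
    neighbors = majority[np.unique(neighbor_rows)]
    return np.union1d(minority, neighbors)


def fit_brf(dataset: Dataset, config: BrfConfig) -> BrfModel:
    """Grow the two sub-forests on bootstrap samples; deterministic per seed.

    Each tree subsamples ceil(sqrt(d)) candidate features per split.  The
    full trees come first, then the critical trees.  Aborts if the critical
    set contains a single class (no discriminative tree can be grown).
    """
    rng = np.random.default_rng(config.seed)
    critical: np.ndarray = np.arange(dataset.n_samples)
    if config.n_critical_trees > 0:
        critical = find_critical_set(dataset, config.k)
        if len(np.unique(dataset.y[critical])) < 2:
            raise ValueError(
                "critical set contains a single class; cannot grow "
                "discriminative critical trees")
    max_features = math.ceil(math.sqrt(dataset.n_features))
    X32 = dataset.X.astype(np.float32)

    trees, tags = [], []
    pools = ([np.arange(dataset.n_samples)] * config.n_full_trees
             + [critical] * config.n_critical_trees)
    labels = [FULL] * config.n_full_trees + [CRITICAL] * config.n_critical_trees
    for pool, tag in zip(pools, labels):
        boot = pool[rng.integers(0, pool.size, size=pool.size)]
        tree = DecisionTreeClassifier(
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X32[boot], dataset.y[boot])
        trees.append(tree)
        tags.append(tag)
    return BrfModel(trees=trees, tags=tags, config=config,
                    critical_indices=critical,
                    feature_names=list(dataset.feature_names))


def brf_predict(model: BrfModel, X) -> np.ndarray:
    """Unweighted majority vote over all trees; ties -> positive class."""
    X32 = np.asarray(np.atleast_2d(X), dtype=np.float32)
    if X32.shape[1] != len(model.feature_names):
        raise ValueError(
            f"query has {X32.shape[1]} features, model expects "
            f"{len(model.feature_names)}")
    votes = np.zeros(X32.shape[0], dtype=np.int64)
    for tree in model.trees:
        votes += tree.predict(X32).astype(np.int64)
    return (2 * votes >= model.n_trees).astype(np.int64)
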