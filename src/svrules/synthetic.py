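"""Synthetic imbalanced tabular data with known ground truth.

Two generators cover the structures the pipeline is designed for:

* ``generate_planted`` — features uniform on [0, 1]^d, positives defined by a
  union of axis-aligned boxes (the "planted" rules), independent label-flip
  noise, and an exact negative:positive ratio achieved by rejection sampling
  on the observed labels (equivalent to subsampling, so the planted geometry
  is untouched).  Because the ground truth *is* an axis-aligned rule set,
  rule recovery by the pipeline is well defined.
* ``generate_gaussian`` — two spherical Gaussian clusters at a requested
  imbalance, for margin/separability checks.

Both are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from svrules.rule_extraction import Condition, Rule, rule_matches
from svrules.tabular_io import Dataset

_MAX_BATCHES = 500


@dataclass
class PlantedRuleSpec:
    """Ground-truth description of a planted-rule dataset.

    ``true_rules`` are positive-label rules (axis-aligned boxes); a sample's
    noiseless label is 1 iff it satisfies any of them.  ``imbalance_target``
    is the desired negative:positive ratio of the *observed* labels;
    ``noise_rate`` is the independent flip probability applied before the
    ratio is enforced.
    """

    n: int
    d: int
    true_rules: list[Rule]
    noise_rate: float = 0.0
    imbalance_target: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if self.imbalance_target < 1:
            raise ValueError("imbalance_target must be >= 1")
        if self.n <= 0 or self.d <= 0:
            raise ValueError("n and d must be positive")
        for rule in self.true_rules:
            for c in rule.conditions:
                if c.feature >= self.d:
                    raise ValueError(
                        f"condition references feature {c.feature} >= d={self.d}")


def planted_labels(true_rules: list[Rule], X: np.ndarray) -> np.ndarray:
    """Noiseless labels: 1 iff any planted rule is satisfied."""
    X = np.atleast_2d(X)
    lab = np.zeros(X.shape[0], dtype=np.int64)
    for rule in true_rules:
        lab |= rule_matches(rule, X).astype(np.int64)
    return lab


def default_planted_spec(n: int = 3000, d: int = 6, noise_rate: float = 0.05,
                         imbalance_target: float = 6.0,
                         seed: int = 0) -> PlantedRuleSpec:
    """Study-condition default: two positive boxes in six dimensions.

    The two boxes jointly cover about 20% of the unit cube, comfortably above
    the positive rate implied by the 1:6 imbalance, so the ratio is reachable
    by rejection for any seed.  With fewer than four features the boxes fall
    back to the available dimensions (a single half-space rule when d = 1).
    """
    if d >= 4:
        rules = [
            Rule(conditions=(Condition(0, ">", 0.7), Condition(1, ">", 0.6)),
                 label=1),
            Rule(conditions=(Condition(2, "<=", 0.25), Condition(3, "<=", 0.35)),
                 label=1),
        ]
    elif d == 3:
        rules = [
            Rule(conditions=(Condition(0, ">", 0.7), Condition(1, ">", 0.6)),
                 label=1),
            Rule(conditions=(Condition(2, "<=", 0.2),), label=1),
        ]
    elif d == 2:
        rules = [
            Rule(conditions=(Condition(0, ">", 0.7), Condition(1, ">", 0.6)),
                 label=1),
            Rule(conditions=(Condition(0, "<=", 0.25), Condition(1, "<=", 0.35)),
                 label=1),
        ]
    else:
        rules = [Rule(conditions=(Condition(0, ">", 0.7),), label=1)]
    return PlantedRuleSpec(n=n, d=d, true_rules=rules, noise_rate=noise_rate,
                           imbalance_target=imbalance_target, seed=seed)


def generate_planted(spec: PlantedRuleSpec) -> tuple[Dataset, PlantedRuleSpec]:
    """Draw a planted-rule dataset matching ``spec``; returns (data, truth).

    Observed class counts are exact: ``n_pos = round(n / (1 + ratio))``
    positives and ``n - n_pos`` negatives, collected by rejection from an
    i.i.d. uniform stream.  Raises if the planted boxes cover (almost) none
    or (almost) all of the cube so that one class never appears within the
    iteration budget.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n / (1.0 + spec.imbalance_target)))
    n_pos = max(n_pos, 1)
    n_neg = spec.n - n_pos

    pos_rows, neg_rows = [], []
    got_pos = got_neg = 0
    batch = max(4 * spec.n, 1000)
    for _ in range(_MAX_BATCHES):
        X = rng.random((batch, spec.d))
        clean = planted_labels(spec.true_rules, X)
        flips = rng.random(batch) < spec.noise_rate
        obs = clean ^ flips.astype(np.int64)
        if got_pos < n_pos:
            take = X[obs == 1][: n_pos - got_pos]
            pos_rows.append(take)
            got_pos += take.shape[0]
        if got_neg < n_neg:
            take = X[obs == 0][: n_neg - got_neg]
            neg_rows.append(take)
            got_neg += take.shape[0]
        if got_pos >= n_pos and got_neg >= n_neg:
            break
    else:
        raise RuntimeError(
            "could not reach the requested class ratio: planted rules cover "
            "almost none or almost all of the feature space")

    X = np.vstack(pos_rows + neg_rows)
    y = np.concatenate([np.ones(n_pos, dtype=np.int64),
                        np.zeros(n_neg, dtype=np.int64)])
    perm = rng.permutation(spec.n)
    names = [f"x{j}" for j in range(spec.d)]
    return Dataset(X[perm], y[perm], names), spec


def generate_gaussian(n: int, d: int, class_means, class_sd: float,
                      imbalance_target: float, seed: int = 0) -> Dataset:
    """Two spherical Gaussian clusters at the requested negative:positive ratio.

    ``class_means`` is a pair (negative mean, positive mean) of length-``d``
    vectors (scalars are broadcast).
    """
    mean_neg, mean_pos = (np.broadcast_to(np.asarray(m, dtype=float), (d,))
                          for m in class_means)
    if np.allclose(mean_neg, mean_pos) and class_sd <= 0:
        raise ValueError("degenerate configuration: identical means, zero sd")
    if imbalance_target < 1:
        raise ValueError("imbalance_target must be >= 1")
    rng = np.random.default_rng(seed)
    n_pos = max(int(round(n / (1.0 + imbalance_target))), 1)
    n_neg = n - n_pos
    X = np.vstack([
        rng.normal(mean_pos, class_sd, size=(n_pos, d)),
        rng.normal(mean_neg, class_sd, size=(n_neg, d)),
    ])
    y = np.concatenate([np.ones(n_pos, dtype=np.int64),
                        np.zeros(n_neg, dtype=np.int64)])
    perm = rng.permutation(n)
    return Dataset(X[perm], y[perm], [f"x{j}" for j in range(d)])
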