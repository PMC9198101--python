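"""Two-stage reduction of a redundant rule pool into an ordered decision list.

Stage 1 — condition pruning.  For each rule, conditions are revisited in
stored (root-to-leaf) order.  Dropping condition j changes the rule's error
rate from err_0 to err_-j; the relative change

    D_j = (err_-j - err_0) / max(err_0, s)

with stabilizer s > 0 measures how much the condition contributes.  If D_j
falls below the threshold (0.05 by default) the condition is removed and
err_0 is updated to err_-j; otherwise it is kept.  Removing a conjunct can
only widen the covered set, so coverage is non-decreasing across pruning.

Stage 2 — rule selection.  Rules whose training coverage falls below g are
discarded, a default rule (empty conditions, current majority label L*) is
appended, and rules are chosen greedily: each iteration recomputes every
remaining rule's error rate on the *remaining* training samples, selects the
minimizer, removes the samples it covers, and updates L* to the majority of
what is left.  Selection stops when the default rule wins (it is appended
as-is) or the training set is exhausted (the default is appended with its
original label).  The result is a decision list evaluated first-match-wins,
total by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from svrules.rule_extraction import (
    Rule,
    RuleSet,
    coverage_matrix,
    rule_matches,
)
from svrules.tabular_io import Dataset


@dataclass
class PruneConfig:
    """Condition-pruning knobs: acceptance threshold, stabilizer s, pass mode."""

    d_threshold: float = 0.05
    s: float = 0.01
    passes: str = "single"

    def __post_init__(self):
        if self.d_threshold <= 0:
            raise ValueError("d_threshold must be positive")
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.passes not in ("single", "fixpoint"):
            raise ValueError("passes must be 'single' or 'fixpoint'")


@dataclass
class DecisionList:
    """Ordered selected rules ending in exactly one default rule."""

    rules: list[Rule]
    g: float

    def __post_init__(self):
        defaults = [r for r in self.rules if r.is_default]
        if len(defaults) != 1 or not self.rules[-1].is_default:
            raise ValueError("a decision list ends in exactly one default rule")

    def __len__(self) -> int:
        return len(self.rules)


def _masked_error(mask: np.ndarray, y: np.ndarray, label: int) -> float:
    covered = int(mask.sum())
    if covered == 0:
        return 1.0
    return float((y[mask] != label).sum() / covered)


def prune_conditions(rule: Rule, dataset: Dataset,
                     config: PruneConfig | None = None) -> Rule:
    """Drop conditions whose removal barely changes the rule's error rate.

    Single pass in stored order by default; ``passes='fixpoint'`` repeats
    until no condition is removed.  The returned rule carries refreshed
    ``err`` and ``coverage`` on ``dataset``.
    """
    config = config or PruneConfig()
    if not rule.conditions:
        return _rescore(rule, dataset)

    masks = [rule_matches(Rule(conditions=(c,), label=rule.label), dataset.X)
             for c in rule.conditions]
    active = list(range(len(rule.conditions)))

    def error_of(indices) -> float:
        if not indices:
            mask = np.ones(dataset.n_samples, dtype=bool)
        else:
            mask = np.logical_and.reduce([masks[i] for i in indices])
        return _masked_error(mask, dataset.y, rule.label)

    while True:
        err0 = error_of(active)
        removed_any = False
        for j in list(active):
            if not active:
                break
            candidate = [i for i in active if i != j]
            err_minus = error_of(candidate)
            d_j = (err_minus - err0) / max(err0, config.s)
            if d_j < config.d_threshold:
                active = candidate
                err0 = err_minus
                removed_any = True
        if config.passes == "single" or not removed_any:
            break

    kept = tuple(rule.conditions[i] for i in active)
    return _rescore(replace(rule, conditions=kept), dataset)


def _rescore(rule: Rule, dataset: Dataset) -> Rule:
    mask = rule_matches(rule, dataset.X)
    rule = replace(rule)
    rule.coverage = float(mask.mean())
    rule.err = _masked_error(mask, dataset.y, rule.label)
    return rule


def _majority_label(y: np.ndarray) -> int:
    # ties resolve to the positive class, consistent with the pipeline's
    # detection-oriented tie rules
    pos = int(y.sum())
    return 1 if pos * 2 >= y.size else 0


def filter_by_coverage(ruleset: RuleSet, dataset: Dataset, g: float) -> RuleSet:
    """Drop rules with training coverage < g and append the default rule.

    The default rule has no conditions and predicts the training-set
    majority label; it is the only rule flagged ``is_default``.
    """
    if not 0 <= g <= 1:
        raise ValueError("g must lie in [0, 1]")
    kept = []
    for rule in ruleset.rules:
        scored = _rescore(rule, dataset)
        if scored.coverage >= g:
            kept.append(scored)
    default = Rule(conditions=(), label=_majority_label(dataset.y),
                   is_default=True)
    default = _rescore(default, dataset)
    return RuleSet(rules=kept + [default], n_trees=ruleset.n_trees)


def greedy_select(ruleset_prime: RuleSet, dataset: Dataset,
                  g: float = 0.0) -> DecisionList:
    """Sequential-covering selection of a decision list (see module docstring).

    ``ruleset_prime`` must contain exactly one default rule.  Duplicate
    rules (identical conditions and label) are collapsed before selection.
    Ties on the per-iteration error rate are broken by higher coverage of
    the remaining samples, then fewer conditions, then pool order; a stored
    rule wins an exact tie against the fallback default rule.
    """
    defaults = [r for r in ruleset_prime.rules if r.is_default]
    if len(defaults) != 1:
        raise ValueError("ruleset must contain exactly one default rule")
    initial_label = defaults[0].label

    seen: set = set()
    pool: list[Rule] = []
    for rule in ruleset_prime.rules:
        # condition pruning can strip a rule down to an empty conjunction;
        # such a rule duplicates the default's structure with a frozen label,
        # so the adaptive default subsumes it
        if rule.is_default or not rule.conditions:
            continue
        key = rule.key()
        if key not in seen:
            seen.add(key)
            pool.append(rule)

    y = dataset.y
    n = dataset.n_samples
    M = coverage_matrix(pool, dataset.X)  # (K, n)
    n_conds = np.array([len(r.conditions) for r in pool], dtype=np.int64)
    remaining = np.ones(n, dtype=bool)
    alive = np.ones(len(pool), dtype=bool)
    label_star = initial_label

    selected: list[Rule] = []
    order = 0

    def append(rule: Rule, err: float, cov_frac: float) -> None:
        nonlocal order
        rule = replace(rule, selection_order=order, err=err, coverage=cov_frac)
        selected.append(rule)
        order += 1

    while True:
        n_rem = int(remaining.sum())
        if n_rem == 0:
            # training set exhausted: default reverts to its initial label
            append(Rule(conditions=(), label=initial_label, is_default=True),
                   err=0.0, cov_frac=1.0)
            break
        default_err = float((y[remaining] != label_star).sum() / n_rem)

        # the default is the fallback: a stored rule that ties it exactly on
        # error and coverage is preferred, otherwise the exhausted-training-
        # set stop branch could never trigger
        best_idx = -1  # -1 encodes the default rule
        best_key = (default_err, -float(n_rem), np.inf, np.inf)
        if alive.any():
            cov = M[:, remaining].sum(axis=1)
            mis = (M[:, remaining]
                   & (y[remaining][None, :] != np.array([r.label for r in pool])[:, None])
                   ).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                errs = np.where(cov > 0, mis / np.maximum(cov, 1), 1.0)
            for i in np.nonzero(alive)[0]:
                key = (float(errs[i]), -float(cov[i]), int(n_conds[i]), float(i))
                if key < best_key:
                    best_key, best_idx = key, int(i)

        if best_idx == -1:
            append(Rule(conditions=(), label=label_star, is_default=True),
                   err=default_err, cov_frac=1.0)
            break

        rule = pool[best_idx]
        cov_count = int(M[best_idx, remaining].sum())
        append(rule, err=float(best_key[0]), cov_frac=cov_count / n_rem)
        remaining &= ~M[best_idx]
        alive[best_idx] = False
        if remaining.any():
            label_star = _majority_label(y[remaining])

    return DecisionList(rules=selected, g=g)


def decision_list_predict(dlist: DecisionList, X) -> np.ndarray:
    """First rule (in selection order) whose conditions a sample satisfies fires."""
    X = np.atleast_2d(X)
    out = np.empty(X.shape[0], dtype=np.int64)
    unassigned = np.ones(X.shape[0], dtype=bool)
    for rule in dlist.rules:
        hit = unassigned & rule_matches(rule, X)
        out[hit] = rule.label
        unassigned &= ~hit
        if not unassigned.any():
            break
    return out


def reduce_ruleset(ruleset: RuleSet, dataset: Dataset,
                   prune_config: PruneConfig | None = None,
                   g: float = 0.01) -> DecisionList:
    """Full reduction: prune every rule's conditions, filter by coverage,
    then greedily select the decision list."""
    if not ruleset.rules:
        raise ValueError("cannot reduce an empty ruleset")
    prune_config = prune_config or PruneConfig()
    pruned = RuleSet(
        rules=[prune_conditions(r, dataset, prune_config) for r in ruleset.rules],
        n_trees=ruleset.n_trees)
    filtered = filter_by_coverage(pruned, dataset, g)
    return greedy_select(filtered, dataset, g=g)
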