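"""Harvest IF-THEN rules from decision-tree paths and score them.

Every root-to-leaf path of a fitted binary tree becomes one conjunctive rule:
left branches contribute ``feature <= threshold`` conditions, right branches
the strict ``feature > threshold`` complement, and the rule's label is the
leaf's majority class.  This convention makes a tree's rule set bit-exactly
equivalent to the tree itself, so a forest's rules reproduce its vote.

Rule statistics follow the standard definitions: coverage is the fraction of
reference samples satisfying all conditions, and the error rate is the
proportion of misjudged samples among the covered ones (a rule covering
nothing is assigned error 1.0 so it can never win a selection round).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from svrules.tabular_io import Dataset

LE = "<="
GT = ">"


@dataclass(frozen=True)
class Condition:
    """A single axis-aligned threshold predicate ``feature (<=|>) threshold``."""

    feature: int
    op: str
    threshold: float

    def __post_init__(self):
        if self.op not in (LE, GT):
            raise ValueError(f"op must be '<=' or '>', got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class Rule:
    """Conjunction of conditions (root-to-leaf order) with a class label.

    ``err`` and ``coverage`` are statistics on a reference dataset;
    ``tree_index``/``subforest`` record provenance inside the forest.
    """

    conditions: tuple[Condition, ...]
    label: int
    err: float | None = None
    coverage: float | None = None
    tree_index: int | None = None
    subforest: str | None = None
    selection_order: int | None = None
    is_default: bool = False

    def key(self) -> tuple:
        """Identity used to collapse duplicate rules."""
        return (tuple((c.feature, c.op, c.threshold) for c in self.conditions),
                self.label)


@dataclass
class RuleSet:
    """Unordered pool of rules with provenance, as extracted from a forest."""

    rules: list[Rule]
    n_trees: int | None = None

    def __len__(self) -> int:
        return len(self.rules)


def _as_float32(X) -> np.ndarray:
    # trees are trained on float32 copies of the data; matching uses the same
    # representation so rule evaluation agrees with the trees bit-for-bit
    return np.asarray(X, dtype=np.float32)


def rule_matches(rule: Rule, X) -> np.ndarray:
    """Boolean mask of samples satisfying every condition (empty rule: all)."""
    X32 = _as_float32(np.atleast_2d(X))
    mask = np.ones(X32.shape[0], dtype=bool)
    for c in rule.conditions:
        col = X32[:, c.feature]
        mask &= (col <= c.threshold) if c.op == LE else (col > c.threshold)
    return mask


def coverage_matrix(rules, X) -> np.ndarray:
    """(n_rules, n_samples) boolean coverage matrix."""
    X32 = _as_float32(np.atleast_2d(X))
    return np.stack([rule_matches(r, X32) for r in rules]) if rules else \
        np.zeros((0, X32.shape[0]), dtype=bool)


def rule_coverage(rule: Rule, dataset: Dataset) -> float:
    if dataset.n_samples == 0:
        raise ValueError("coverage is undefined on an empty dataset")
    return float(rule_matches(rule, dataset.X).mean())


def rule_error_rate(rule: Rule, dataset: Dataset) -> float:
    """Misjudged covered samples / covered samples; 1.0 when nothing is covered."""
    if dataset.n_samples == 0:
        raise ValueError("error rate is undefined on an empty dataset")
    mask = rule_matches(rule, dataset.X)
    covered = int(mask.sum())
    if covered == 0:
        return 1.0
    return float((dataset.y[mask] != rule.label).sum() / covered)


def tree_to_rules(tree, tree_index: int | None = None,
                  subforest: str | None = None) -> list[Rule]:
    """One rule per leaf of a fitted scikit-learn decision tree.

    Left children carry ``feature <= threshold``, right children the strict
    complement; the rule label is the class the leaf itself predicts.
    """
    t = tree.tree_
    classes = np.asarray(tree.classes_)
    rules: list[Rule] = []

    def walk(node: int, conds: list[Condition]) -> None:
        if t.children_left[node] == -1:  # leaf
            label = int(classes[int(np.argmax(t.value[node][0]))])
            rules.append(Rule(conditions=tuple(conds), label=label,
                              tree_index=tree_index, subforest=subforest))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        walk(t.children_left[node], conds + [Condition(f, LE, thr)])
        walk(t.children_right[node], conds + [Condition(f, GT, thr)])

    walk(0, [])
    return rules


def merge_conditions(rule: Rule) -> Rule:
    """Canonicalize repeated splits on one feature to the tightest interval.

    Keeps the minimum of the ``<=`` thresholds and the maximum of the ``>``
    thresholds per feature; the covered set is unchanged.  Condition order
    follows first occurrence along the original path.
    """
    upper: dict[int, float] = {}
    lower: dict[int, float] = {}
    order: list[tuple[int, str]] = []
    for c in rule.conditions:
        store = upper if c.op == LE else lower
        key = (c.feature, c.op)
        if c.feature not in store:
            order.append(key)
            store[c.feature] = c.threshold
        else:
            store[c.feature] = (min if c.op == LE else max)(
                store[c.feature], c.threshold)
    for f in set(upper) & set(lower):
        # a real tree path can never assert x > a and x <= b with b <= a
        assert lower[f] < upper[f], (
            f"contradictory interval on feature {f}: > {lower[f]} and <= {upper[f]}")
    merged = tuple(
        Condition(f, op, upper[f] if op == LE else lower[f]) for f, op in order)
    return replace(rule, conditions=merged)


def extract_initial_ruleset(model, dataset: Dataset) -> RuleSet:
    """Merged rules from every tree of a BRF, scored on ``dataset``.

    The reference dataset for per-rule error and coverage is a configuration
    choice of the caller (original training data by default in the pipeline).
    """
    rules: list[Rule] = []
    for i, (tree, tag) in enumerate(zip(model.trees, model.tags)):
        for rule in tree_to_rules(tree, tree_index=i, subforest=tag):
            rule = merge_conditions(rule)
            rule.err = rule_error_rate(rule, dataset)
            rule.coverage = rule_coverage(rule, dataset)
            rules.append(rule)
    return RuleSet(rules=rules, n_trees=len(model.trees))


def ruleset_predict(ruleset: RuleSet, X) -> np.ndarray:
    """Forest vote reconstructed from rules alone.

    Within each source tree exactly one rule matches any sample (the leaves
    partition feature space), so summing matches of label-1 rules counts the
    trees voting positive.  Ties go to the positive class, as in the forest.
    """
    X32 = _as_float32(np.atleast_2d(X))
    n_trees = ruleset.n_trees
    if n_trees is None:
        n_trees = len({r.tree_index for r in ruleset.rules})
    votes = np.zeros(X32.shape[0], dtype=np.int64)
    for rule in ruleset.rules:
        if rule.label == 1:
            votes += rule_matches(rule, X32)
    return (2 * votes >= n_trees).astype(np.int64)
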