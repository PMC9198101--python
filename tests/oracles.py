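"""Independent reference implementations used as test oracles.

Everything here is written with plain Python loops, straight from the
mathematical definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math


def satisfies(conditions, x) -> bool:
    """Plain-loop condition check: conditions are (feature, op, threshold)."""
    for f, op, thr in conditions:
        v = float(x[f])
        if op == "<=":
            if not v <= thr:
                return False
        else:
            if not v > thr:
                return False
    return True


def rule_error(conditions, label, X, y) -> float:
    covered = [i for i in range(len(y)) if satisfies(conditions, X[i])]
    if not covered:
        return 1.0
    wrong = sum(1 for i in covered if y[i] != label)
    return wrong / len(covered)


def prune_trace(conditions, label, X, y, d_threshold=0.05, s=0.01):
    """Sequential condition pruning, literal transcription.

    Returns (kept conditions, list of (condition, D_j, removed) decisions).
    """
    active = list(conditions)
    decisions = []
    err0 = rule_error(active, label, X, y)
    for cond in list(conditions):
        if cond not in active:
            continue
        candidate = [c for c in active if c != cond]
        err_minus = rule_error(candidate, label, X, y)
        d_j = (err_minus - err0) / max(err0, s)
        removed = d_j < d_threshold
        decisions.append((cond, d_j, removed))
        if removed:
            active = candidate
            err0 = err_minus
    return active, decisions


def greedy_reference(rules, X, y, default_label):
    """Literal transcription of the sequential rule-filtering pseudocode.

    ``rules`` are (conditions, label) pairs (the default rule is implicit).
    Ties on the minimum error rate resolve to higher coverage of the
    remaining samples, then fewer conditions, then pool order; the default
    rule has full coverage and no conditions.  Returns the ordered output as
    (conditions, label, is_default) triples.
    """
    remaining = list(range(len(y)))
    pool = list(range(len(rules)))
    l_star = default_label
    initial = default_label
    out = []
    while True:
        if not remaining:
            out.append(((), initial, True))
            return out
        n_rem = len(remaining)
        default_err = sum(1 for i in remaining if y[i] != l_star) / n_rem
        # default candidate: (err, -coverage, n_conditions, order); stored
        # rules win exact ties against the fallback default
        best_key = (default_err, -float(n_rem), math.inf, math.inf)
        best = None
        for order, ri in enumerate(pool):
            conds, label = rules[ri]
            covered = [i for i in remaining if satisfies(conds, X[i])]
            if covered:
                err = sum(1 for i in covered if y[i] != label) / len(covered)
            else:
                err = 1.0
            key = (err, -float(len(covered)), len(conds), order)
            if key < best_key:
                best_key, best = key, ri
        if best is None:
            out.append(((), l_star, True))
            return out
        conds, label = rules[best]
        out.append((tuple(conds), label, False))
        remaining = [i for i in remaining if not satisfies(conds, X[i])]
        pool.remove(best)
        if remaining:
            pos = sum(1 for i in remaining if y[i] == 1)
            l_star = 1 if 2 * pos >= len(remaining) else 0


def metrics_reference(tp, fp, tn, fn):
    """Straight-from-formula scores with the same degenerate conventions."""
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    rad = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(rad) if rad > 0 else 0.0
    return accuracy, precision, recall, f1, mcc
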