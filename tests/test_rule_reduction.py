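import numpy as np
import pytest

from oracles import greedy_reference, prune_trace, rule_error
from svrules.rule_extraction import Condition, Rule, RuleSet, rule_matches
from svrules.rule_reduction import (
    DecisionList,
    PruneConfig,
    decision_list_predict,
    filter_by_coverage,
    greedy_select,
    prune_conditions,
    reduce_ruleset,
)
from svrules.tabular_io import Dataset


def make(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    return Dataset(X, y, [f"x{j}" for j in range(X.shape[1])])


def as_tuples(rule):
    return tuple((c.feature, c.op, c.threshold) for c in rule.conditions)


class TestPruneConditions:
    def test_no_effect_condition_removed(self, rng):
        X = rng.random((50, 2))
        y = (X[:, 0] > 0.5).astype(int)
        d = make(X, y)
        # second condition never changes the covered set's error
        r = Rule(conditions=(Condition(0, ">", 0.5), Condition(1, "<=", 1.5)),
                 label=1)
        pruned = prune_conditions(r, d, PruneConfig())
        assert pruned.conditions == (Condition(0, ">", 0.5),)

    def test_worked_error_rate_arithmetic(self):
        # err_0 = 0.10 (10 covered, 1 wrong); dropping the first condition
        # gives err_-1 = 0.12 (25 covered, 3 wrong);
        # D_1 = (0.12 - 0.10) / max(0.10, 0.01) = 0.2 >= 0.05 -> keep
        X = np.zeros((40, 2))
        y = np.zeros(40, dtype=int)
        X[:10] = [0.2, 0.2]
        y[:10] = [1] * 9 + [0]
        X[10:25] = [0.2, 0.8]
        y[10:25] = [1] * 13 + [0] * 2
        X[25:] = [0.8, 0.8]
        d = make(X, y)
        rule = Rule(conditions=(Condition(1, "<=", 0.5),
                                Condition(0, "<=", 0.5)), label=1)
        assert rule_error(as_tuples(rule), 1, X, y) == pytest.approx(0.10)
        err_minus = rule_error(as_tuples(rule)[1:], 1, X, y)
        assert err_minus == pytest.approx(0.12)
        d_j = (err_minus - 0.10) / max(0.10, 0.01)
        assert d_j == pytest.approx(0.2)
        cfg = PruneConfig()
        assert cfg.d_threshold == 0.05 and cfg.s == 0.01
        pruned = prune_conditions(rule, d, cfg)
        assert Condition(1, "<=", 0.5) in pruned.conditions

    def test_coverage_non_decreasing(self, rng):
        X = rng.random((120, 3))
        y = rng.integers(0, 2, 120)
        d = make(X, y)
        for _ in range(10):
            conds = tuple(
                Condition(int(rng.integers(0, 3)),
                          "<=" if rng.random() < 0.5 else ">",
                          float(rng.random()))
                for _ in range(int(rng.integers(1, 5))))
            r = Rule(conditions=conds, label=int(rng.integers(0, 2)))
            before = float(rule_matches(r, X).mean())
            after = prune_conditions(r, d, PruneConfig()).coverage
            assert after >= before - 1e-12

    def test_matches_literal_sequential_procedure(self, rng):
        # 12-sample fixture with a 3-condition rule, checked against a
        # plain-loop transcription of the pruning procedure
        X = np.array([
            [0.10, 0.20, 0.90], [0.15, 0.25, 0.10], [0.20, 0.40, 0.80],
            [0.30, 0.45, 0.20], [0.35, 0.60, 0.70], [0.40, 0.70, 0.30],
            [0.55, 0.30, 0.60], [0.60, 0.50, 0.40], [0.70, 0.65, 0.85],
            [0.80, 0.35, 0.15], [0.90, 0.75, 0.55], [0.95, 0.85, 0.25],
        ])
        y = np.array([1, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 0])
        d = make(X, y)
        conds = (Condition(0, "<=", 0.5), Condition(1, "<=", 0.65),
                 Condition(2, ">", 0.15))
        rule = Rule(conditions=conds, label=1)
        kept_ref, decisions = prune_trace(
            [as_tuples(rule)[i] for i in range(3)], 1, X, y)
        pruned = prune_conditions(rule, d, PruneConfig())
        assert as_tuples(pruned) == tuple(kept_ref)
        # the trace itself is meaningful: at least one D_j computed
        assert len(decisions) >= 1

    def test_fixpoint_mode_reaches_stability(self, rng):
        X = rng.random((80, 3))
        y = (X[:, 0] > 0.4).astype(int)
        d = make(X, y)
        r = Rule(conditions=(Condition(0, ">", 0.4), Condition(1, "<=", 0.99),
                             Condition(2, "<=", 0.99)), label=1)
        once = prune_conditions(r, d, PruneConfig(passes="fixpoint"))
        again = prune_conditions(once, d, PruneConfig(passes="fixpoint"))
        assert once.conditions == again.conditions


class TestCoverageFilter:
    def _ruleset(self):
        rules = [
            Rule(conditions=(Condition(0, "<=", 0.5),), label=1),   # cov 0.50
            Rule(conditions=(Condition(0, "<=", 0.03),), label=1),  # cov 0.03
            Rule(conditions=(Condition(0, ">", 0.8),), label=0),    # cov 0.20
        ]
        X = np.linspace(0.005, 0.995, 100)[:, None]
        y = (X[:, 0] <= 0.5).astype(int)
        return RuleSet(rules=rules), make(X, y)

    def test_g_zero_keeps_all(self):
        rs, d = self._ruleset()
        out = filter_by_coverage(rs, d, 0.0)
        assert len(out) == 4  # three rules + default

    def test_g_one_keeps_only_default(self):
        rs, d = self._ruleset()
        out = filter_by_coverage(rs, d, 1.0)
        assert len(out) == 1 and out.rules[0].is_default

    def test_hand_counted_threshold(self):
        rs, d = self._ruleset()
        out = filter_by_coverage(rs, d, 0.05)
        kept = [r for r in out.rules if not r.is_default]
        assert len(kept) == 2
        assert all(r.coverage >= 0.05 for r in kept)

    def test_default_label_is_majority(self):
        rs, d = self._ruleset()
        out = filter_by_coverage(rs, d, 0.0)
        default = out.rules[-1]
        assert default.is_default
        assert default.label == int(d.y.sum() * 2 >= d.n_samples)


class TestGreedySelect:
    def test_default_only_pool(self, rng):
        d = make(rng.random((10, 1)), [0] * 7 + [1] * 3)
        rs = RuleSet(rules=[Rule(conditions=(), label=0, is_default=True)])
        out = greedy_select(rs, d)
        assert len(out) == 1 and out.rules[0].is_default
        assert out.rules[0].label == 0

    def test_perfect_rule_then_default(self):
        # one rule captures all positives with zero error; afterwards the
        # default (on the pure-negative remainder) also has zero error
        X = np.linspace(0, 1, 20)[:, None]
        y = (X[:, 0] > 0.7).astype(int)
        d = make(X, y)
        rs = RuleSet(rules=[
            Rule(conditions=(Condition(0, ">", 0.7),), label=1),
            Rule(conditions=(), label=0, is_default=True),
        ])
        out = greedy_select(rs, d)
        assert len(out) == 2
        assert out.rules[0].label == 1 and not out.rules[0].is_default
        assert out.rules[1].is_default and out.rules[1].label == 0

    def test_exhaustion_resets_default_label(self):
        # two complementary zero-error rules cover every sample; the default
        # is then appended with the *initial* majority label
        X = np.linspace(0, 1, 20)[:, None]
        y = (X[:, 0] > 0.4).astype(int)  # 12 positives: initial L* = 1
        d = make(X, y)
        rs = RuleSet(rules=[
            Rule(conditions=(Condition(0, "<=", 0.4),), label=0),
            Rule(conditions=(Condition(0, ">", 0.4),), label=1),
            Rule(conditions=(), label=1, is_default=True),
        ])
        out = greedy_select(rs, d)
        assert out.rules[-1].is_default
        assert out.rules[-1].label == 1
        assert len(out) == 3

    def test_matches_literal_pseudocode_default_branch(self, rng):
        X = rng.random((20, 2))
        y = ((X[:, 0] > 0.5) ^ (rng.random(20) < 0.15)).astype(int)
        rules = [
            ((0, ">", 0.5),),
            ((0, "<=", 0.5),),
            ((1, ">", 0.6), (0, "<=", 0.8)),
            ((1, "<=", 0.3),),
            ((0, ">", 0.2), (1, ">", 0.2)),
        ]
        labels = [1, 0, 0, 1, 0]
        self._compare_with_reference(X, y, rules, labels)

    def test_matches_literal_pseudocode_exhaustion_branch(self, rng):
        X = rng.random((20, 2))
        y = (X[:, 0] > 0.5).astype(int)
        rules = [
            ((0, ">", 0.5),),
            ((0, "<=", 0.5),),
            ((1, ">", 0.9),),
            ((0, ">", 0.7), (1, "<=", 0.5)),
            ((1, "<=", 0.1),),
        ]
        labels = [1, 0, 0, 1, 0]
        self._compare_with_reference(X, y, rules, labels)

    @staticmethod
    def _compare_with_reference(X, y, rules, labels):
        d = make(X, y)
        default_label = int(y.sum() * 2 >= len(y))
        pool = [Rule(conditions=tuple(Condition(*c) for c in conds),
                     label=lab) for conds, lab in zip(rules, labels)]
        rs = RuleSet(rules=pool + [
            Rule(conditions=(), label=default_label, is_default=True)])
        ours = greedy_select(rs, d)
        ref = greedy_reference(list(zip(rules, labels)), X, y, default_label)
        assert len(ours) == len(ref)
        for got, (conds, lab, is_def) in zip(ours.rules, ref):
            assert as_tuples(got) == tuple(conds)
            assert got.label == lab
            assert got.is_default == is_def

    def test_duplicates_collapse(self, rng):
        X = rng.random((30, 1))
        y = (X[:, 0] > 0.5).astype(int)
        d = make(X, y)
        dup = Rule(conditions=(Condition(0, ">", 0.5),), label=1)
        rs = RuleSet(rules=[dup, Rule(conditions=dup.conditions, label=1),
                            Rule(conditions=(), label=0, is_default=True)])
        out = greedy_select(rs, d)
        stored = [as_tuples(r) for r in out.rules if not r.is_default]
        assert stored.count(as_tuples(dup)) == 1

    def test_terminates_within_pool_size(self, rng):
        X = rng.random((50, 2))
        y = rng.integers(0, 2, 50)
        d = make(X, y)
        pool = [Rule(conditions=(Condition(0, ">", t),), label=int(l))
                for t, l in zip(np.linspace(0.1, 0.9, 9),
                                rng.integers(0, 2, 9))]
        rs = RuleSet(rules=pool + [
            Rule(conditions=(), label=0, is_default=True)])
        out = greedy_select(rs, d)
        assert len(out) <= len(pool) + 1


class TestDecisionListPredict:
    def _list(self):
        rules = [
            Rule(conditions=(Condition(0, "<=", 0.3),), label=1,
                 selection_order=0),
            Rule(conditions=(Condition(1, ">", 0.5),), label=0,
                 selection_order=1),
            Rule(conditions=(Condition(0, ">", 0.6),), label=1,
                 selection_order=2),
            Rule(conditions=(), label=0, is_default=True, selection_order=3),
        ]
        return DecisionList(rules=rules, g=0.0)

    def test_first_match_wins(self):
        dl = self._list()
        # matches rules #0 and #1 -> rule #0 fires
        assert decision_list_predict(dl, [[0.2, 0.9]]).tolist() == [1]

    def test_default_fires_when_nothing_matches(self):
        dl = self._list()
        assert decision_list_predict(dl, [[0.5, 0.2]]).tolist() == [0]

    def test_matches_linear_scan_oracle(self, rng):
        from oracles import satisfies

        dl = self._list()
        Q = rng.random((300, 2))
        expected = []
        for x in Q:
            for r in dl.rules:
                if satisfies(as_tuples(r), x):
                    expected.append(r.label)
                    break
        np.testing.assert_array_equal(decision_list_predict(dl, Q), expected)

    def test_requires_exactly_one_default_last(self):
        with pytest.raises(ValueError, match="default"):
            DecisionList(rules=[Rule(conditions=(), label=0)], g=0.0)


class TestReducePipeline:
    def test_output_never_larger_than_input_plus_default(self, rng):
        X = rng.random((100, 2))
        y = (X[:, 0] > 0.6).astype(int)
        d = make(X, y)
        pool = [Rule(conditions=(Condition(0, ">", t),), label=1)
                for t in np.linspace(0.3, 0.8, 6)]
        out = reduce_ruleset(RuleSet(rules=pool), d, g=0.0)
        assert len(out) <= len(pool) + 1

    def test_single_broad_rule_collapses(self, rng):
        X = rng.random((60, 1))
        y = np.ones(60, dtype=int)
        y[:5] = 0
        d = make(X, y)
        rs = RuleSet(rules=[Rule(conditions=(Condition(0, "<=", 2.0),),
                                 label=1)])
        out = reduce_ruleset(rs, d, g=0.0)
        # the rule prunes to an empty conjunction, so only the default
        # remains and it predicts the majority class
        assert len(out) == 1
        assert out.rules[0].is_default and out.rules[0].label == 1
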