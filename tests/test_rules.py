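"""Rule statistics, coverage semantics and sequential-covering induction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import immunorules as ir
from immunorules.rules import ContingencyTable, ElementaryCondition
from conftest import make_dataset

EC = ElementaryCondition
CT = ContingencyTable


# ---------------------------------------------------------------------------
# coverage semantics
# ---------------------------------------------------------------------------

class TestCovers:
    def test_empty_premise_covers_everyone(self):
        ds = make_dataset({"CD9": [0, 2, np.nan]})
        assert list(ir.covers((), ds)) == list(ds.patients)

    def test_missing_value_fails_condition(self):
        ds = make_dataset({"CD9": [0, 2, np.nan]})
        assert list(ir.covers([EC("CD9", ">", 1)], ds)) == [1]

    def test_conjunction_is_set_intersection(self):
        ds = make_dataset({"NG2": [1, 1, 0, 1, 0, np.nan],
                           "CD24": [2, 9, 3, 4, 1, 2]}, binary={"NG2"})
        premise = [EC("NG2", "=", 1), EC("CD24", "<=", 4)]
        a = set(ir.covers([premise[0]], ds))
        b = set(ir.covers([premise[1]], ds))
        assert set(ir.covers(premise, ds)) == a & b == {0, 3}


class TestContingency:
    def test_covering_nothing(self, eight_patient_labels):
        p = ir.build_decision_problem(eight_patient_labels, "no_aberration")
        t = ir.contingency([EC("CD10", ">", 100)], eight_patient_labels, p)
        assert (t.p, t.n, t.P, t.N) == (0, 0, 3, 5)

    def test_full_coverage(self, eight_patient_labels):
        p = ir.build_decision_problem(eight_patient_labels, "no_aberration")
        t = ir.contingency([EC("CD10", ">=", 0)], eight_patient_labels, p)
        assert (t.p, t.n, t.P, t.N) == (3, 5, 3, 5)

    def test_published_counts_reconstructed(self):
        # IF CD9 > 1 AND CD13 < 3 THEN no ETV6-RUNX1: 170 of 422 covered,
        # 1 of the 52 carriers covered
        premise = (EC("CD9", ">", 1), EC("CD13", "<", 3))
        ds = ir.dataset_matching_counts(premise, "ETV6-RUNX1", 170, 1, 422, 52)
        prob = ir.build_decision_problem(ds, "etv6_runx1")
        t = ir.contingency(premise, ds, prob, prob.secondary_class_name)
        assert (t.p, t.n, t.P, t.N) == (170, 1, 422, 52)

    def test_excluded_patients_ignored(self, eight_patient_labels):
        p = ir.build_decision_problem(eight_patient_labels, "etv6_vs_hyperdiploidy")
        t = ir.contingency((), eight_patient_labels, p)
        assert (t.P, t.N) == (2, 2)


# ---------------------------------------------------------------------------
# rule statistics
# ---------------------------------------------------------------------------

class TestC2:
    @pytest.mark.parametrize("table,expected", [
        (CT(10, 0, 10, 10), 1.0),                       # perfect rule
        (CT(0, 10, 10, 10), -0.5),
        (CT(170, 1, 422, 52), 0.6640315699931565),
    ])
    def test_values(self, table, expected):
        assert ir.c2(table) == pytest.approx(expected, abs=1e-12)

    def test_undefined_on_empty_cover(self):
        with pytest.raises(ValueError):
            ir.c2(CT(0, 0, 5, 5))

    @settings(derandomize=True, max_examples=300)
    @given(st.integers(1, 40), st.integers(1, 40),
           st.integers(0, 40), st.integers(0, 40))
    def test_bounded_by_one_with_equality_iff_perfect(self, P, N, p, n):
        p, n = min(p, P), min(n, N)
        if p + n == 0:
            return
        q = ir.c2(CT(p, n, P, N))
        assert q <= 1.0 + 1e-12
        assert (abs(q - 1.0) < 1e-12) == (p == P and n == 0)

    def test_monotone_in_p_and_n_at_fixed_cover(self):
        # increasing p (decreasing n) at fixed p+n strictly increases C2
        P, N, cover = 20, 30, 12
        qs = [ir.c2(CT(p, cover - p, P, N)) for p in range(cover + 1)]
        assert all(a < b for a, b in zip(qs, qs[1:]))


class TestPrecisionCoverage:
    def test_published_tree_rule_precision(self):
        # 18 covered, 17 with the aberration
        assert ir.precision(CT(17, 1, 52, 422)) == pytest.approx(17 / 18)

    def test_published_coverage_69_percent(self):
        assert ir.coverage(CT(405, 1, 588, 17)) == pytest.approx(0.6888, abs=5e-4)

    def test_zero_precision_and_errors(self):
        assert ir.precision(CT(0, 5, 10, 10)) == 0.0
        with pytest.raises(ValueError):
            ir.precision(CT(0, 0, 10, 10))


class TestOddsRatio:
    @pytest.mark.parametrize("table,expected", [
        (CT(170, 1, 422, 52), 34.40),
        (CT(405, 1, 588, 17), 35.41),
    ])
    def test_published_values(self, table, expected):
        assert ir.odds_ratio(table) == pytest.approx(expected, abs=0.05)

    def test_zero_negative_cell_diverges(self):
        assert ir.odds_ratio(CT(6, 0, 10, 20)) == math.inf

    def test_fully_degenerate_undefined(self):
        with pytest.raises(ValueError):
            ir.odds_ratio(CT(0, 0, 10, 20))

    def test_scaling_invariance_via_haldane_limit(self):
        # plain OR is scale-free; the Haldane-corrected variant approaches
        # it as all four cells grow
        base = CT(8, 3, 20, 30)
        plain = ir.odds_ratio(base)
        for s in (1, 10, 100):
            scaled = CT(8 * s, 3 * s, 20 * s, 30 * s)
            assert ir.odds_ratio(scaled) == pytest.approx(plain)
        h = [abs(ir.odds_ratio(CT(8 * s, 3 * s, 20 * s, 30 * s), haldane=True)
                 - plain) for s in (1, 10, 100)]
        assert h[0] > h[1] > h[2]


class TestFisher:
    def test_two_of_two_drawn(self):
        # all C(4,2)=6 equally likely draws; only one takes both positives
        assert ir.fisher_p(CT(2, 0, 2, 2)) == pytest.approx(1 / 6)

    def test_published_significance(self):
        assert ir.fisher_p(CT(170, 1, 422, 52)) == pytest.approx(5.0e-10, rel=0.05)

    def test_no_enrichment_close_to_one(self):
        assert ir.fisher_p(CT(1, 1, 5, 5)) > 0.5

    def test_matches_exhaustive_enumeration_small_tables(self):
        # independent oracle: sum the hypergeometric tail with math.comb
        for P in range(1, 12):
            for N in range(1, 13 - P):
                for k in range(1, P + N + 1):
                    for p in range(max(0, k - N), min(P, k) + 1):
                        expected = sum(
                            math.comb(P, i) * math.comb(N, k - i)
                            for i in range(p, min(P, k) + 1)
                        ) / math.comb(P + N, k)
                        got = ir.fisher_p(CT(p, k - p, P, N))
                        assert got == pytest.approx(expected, rel=1e-9), (p, k, P, N)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert ir.adjust_pvalues([0.04]) == [pytest.approx(0.04)]

    def test_benjamini_hochberg_textbook(self):
        assert ir.adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03] * 3)

    def test_equal_ps_stay_equal(self):
        out = ir.adjust_pvalues([0.02, 0.02, 0.02, 0.02])
        assert len(set(np.round(out, 12))) == 1


# ---------------------------------------------------------------------------
# induction
# ---------------------------------------------------------------------------

def _separable():
    return make_dataset({"X": [0, 1, 2, 3, 4, 5, 6, 7],
                         "Z": [1, 0, 1, 0, 1, 0, 1, 0]},
                        labels={"KMT2A": [0, 0, 0, 0, 1, 1, 1, 1]})


class TestGrowRule:
    def test_perfect_separator_found(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        rule = ir.grow_rule(ds, prob)
        assert rule.stats.c2 == pytest.approx(1.0)
        assert len(rule.premise) == 1 and rule.premise[0].attribute == "X"

    def test_matches_bruteforce_on_toy(self, rng):
        # exhaustive oracle over all premises of length <= 2
        ds = make_dataset(
            {"A": [0, 0, 1, 1, 2, 2, 3, 3], "B": [0, 1, 0, 1, 0, 1, 0, 1]},
            labels={"KMT2A": [1, 1, 1, 0, 0, 1, 0, 0]})
        prob = ir.build_decision_problem(ds, "kmt2a")
        rule = ir.grow_rule(ds, prob)
        best = _exhaustive_best2(ds, prob)
        assert rule.stats.c2 >= best - 1e-12

    def test_enforced_condition_kept_once(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        rule = ir.grow_rule(ds, prob, enforced=(EC("X", ">", 2),),
                            forbidden_attributes=("X",))
        assert [c for c in rule.premise if c.attribute == "X"] == [EC("X", ">", 2)]

    def test_enforced_covering_no_positives_rejected(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        with pytest.raises(ValueError, match="no positive"):
            ir.grow_rule(ds, prob, enforced=(EC("X", "<", 0),))


def _exhaustive_best2(ds, prob):
    from immunorules.rules import _ProblemView, _candidate_conditions, c2

    view = _ProblemView(ds, prob, prob.primary_class_name)
    row = np.ones(view.n_rows, bool)
    cands = list(_candidate_conditions(view, view.cover(()), set(view.marker_names)))
    best = -np.inf
    for k in (1, 2):
        for combo in itertools.combinations(cands, k):
            t = view.table(view.cover(combo), row)
            if t.p + t.n:
                best = max(best, c2(t))
    return best


class TestPruneRule:
    def test_redundant_condition_removed(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        fat = ir.evaluate_rule(
            ir.Rule((EC("X", ">", 3.5), EC("X", ">", 2.5)), "KMT2A"), ds, prob)
        pruned = ir.prune_rule(fat, ds, prob)
        assert len(pruned.premise) == 1
        assert pruned.stats.c2 >= fat.stats.c2

    def test_minimal_rule_is_fixed_point(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        rule = ir.grow_rule(ds, prob)
        assert ir.prune_rule(rule, ds, prob).premise == rule.premise

    def test_pruning_never_decreases_quality(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 13))
            ds = make_dataset(
                {"A": rng.integers(0, 4, n), "B": rng.integers(0, 4, n)},
                labels={"KMT2A": _both_classes(rng, n)})
            prob = ir.build_decision_problem(ds, "kmt2a")
            conds = []
            for _ in range(int(rng.integers(1, 4))):
                attr = rng.choice(["A", "B"])
                rel = rng.choice(["<", "<=", ">", ">="])
                conds.append(EC(attr, rel, float(rng.integers(0, 4))))
            rule = ir.evaluate_rule(ir.Rule(tuple(conds), "KMT2A"), ds, prob)
            if rule.stats.table.p + rule.stats.table.n == 0:
                continue
            pruned = ir.prune_rule(rule, ds, prob)
            assert pruned.stats.c2 >= rule.stats.c2 - 1e-12


def _both_classes(rng, n):
    y = rng.integers(0, 2, n)
    while y.sum() in (0, n):
        y = rng.integers(0, 2, n)
    return y


class TestInduceRuleset:
    def test_separable_data_fully_covered(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        rules = ir.induce_ruleset(ds, prob, mincov=1)
        covered = set()
        for r in rules:
            assert r.stats.table.n == 0
            covered |= set(ir.covers(r.premise, ds))
        assert covered >= {4, 5, 6, 7}

    def test_planted_rule_recovered(self):
        cfg = ir.clean_config(n_patients=300, seed=7)
        ds = ir.generate(cfg)
        rule = cfg.planted_rules[0]  # NG2 = 1 AND CD24 <= 4 => KMT2A
        prob = ir.build_decision_problem(ds, "kmt2a")
        rules = ir.induce_ruleset(ds, prob)
        top = max(rules, key=lambda r: r.stats.c2)
        assert set(ir.covers(top.premise, ds)) == set(ir.covers(rule.conditions, ds))

    def test_mincov_exceeding_class_size_warns(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        with pytest.warns(UserWarning, match="mincov"):
            assert ir.induce_ruleset(ds, prob, mincov=10) == []

    def test_deterministic(self):
        ds = ir.generate(ir.clean_config(n_patients=200, seed=11))
        prob = ir.build_decision_problem(ds, "hyperdiploidy")
        a = ir.induce_ruleset(ds, prob)
        b = ir.induce_ruleset(ds, prob)
        assert [str(r) for r in a] == [str(r) for r in b]

    def test_adjusted_pvalues_attached_and_monotone(self):
        ds = ir.generate(ir.clean_config(n_patients=200, seed=11))
        prob = ir.build_decision_problem(ds, "hyperdiploidy")
        for r in ir.induce_ruleset(ds, prob):
            assert r.stats.adjusted_p >= r.stats.fisher_p


class TestOddsChain:
    def test_single_condition_chain(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        rule = ir.grow_rule(ds, prob)
        chain = ir.odds_chain(rule, ds, prob)
        assert chain == [ir.odds_ratio(rule.stats.table)]

    def test_chain_matches_per_prefix_tables(self):
        ds = make_dataset(
            {"A": [0, 1, 2, 3, 4, 0, 1, 2, 3, 4],
             "B": [1, 1, 1, 0, 0, 0, 0, 1, 1, 0]},
            labels={"KMT2A": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]})
        prob = ir.build_decision_problem(ds, "kmt2a")
        rule = ir.evaluate_rule(
            ir.Rule((EC("A", "<=", 3), EC("B", "=", 1)), "KMT2A"), ds, prob)
        chain = ir.odds_chain(rule, ds, prob)
        # manual prefix tables: A<=3 covers 4 pos, 4 neg; adding B=1 -> 3 pos, 2 neg
        assert chain[0] == pytest.approx(ir.odds_ratio(CT(4, 4, 4, 6)))
        assert chain[1] == pytest.approx(ir.odds_ratio(CT(3, 2, 4, 6)))
        assert chain[-1] == ir.odds_ratio(rule.stats.table)


class TestNegation:
    def test_complete_data_complement(self):
        ds = make_dataset({"CD9": [0, 1, 2, 3], "CD13": [5, 1, 2, 4]},
                          labels={"ETV6-RUNX1": [1, 0, 0, 1]})
        prob = ir.build_decision_problem(ds, "etv6_runx1")
        rule = ir.evaluate_rule(
            ir.Rule((EC("CD9", ">", 1), EC("CD13", "<", 3)),
                    prob.secondary_class_name), ds, prob)
        t = ir.evaluate_negation(rule, ds, prob)
        cover = set(ir.covers(rule.premise, ds))
        assert t.p + t.n == 4 - len(cover)  # De Morgan on complete data

    def test_missing_value_satisfies_neither(self):
        ds = make_dataset({"CD9": [0, 3, np.nan, 2]},
                          labels={"ETV6-RUNX1": [1, 0, 1, 0]})
        prob = ir.build_decision_problem(ds, "etv6_runx1")
        rule = ir.evaluate_rule(ir.Rule((EC("CD9", ">", 1),),
                                        prob.secondary_class_name), ds, prob)
        t = ir.evaluate_negation(rule, ds, prob)
        covered_either = len(ir.covers(rule.premise, ds)) + t.p + t.n
        assert covered_either == 3 < 4  # the missing row is in neither cover

    def test_published_negation_counts(self):
        # negation of the CD9/CD13 rule: 24 carriers and 102 others covered
        ds = ir.dataset_matching_counts(
            (EC("CD9", "<=", 1),), "ETV6-RUNX1", 24, 102, 52, 422,
            conclusion_is_positive=True)
        prob = ir.build_decision_problem(ds, "etv6_runx1")
        t = ir.contingency((EC("CD9", "<=", 1),), ds, prob,
                           prob.primary_class_name)
        assert ir.odds_ratio(t) == pytest.approx(2.69, abs=0.005)


class TestSerialization:
    def test_json_round_trip(self):
        ds = _separable()
        prob = ir.build_decision_problem(ds, "kmt2a")
        rule = ir.grow_rule(ds, prob)
        back = ir.Rule.from_dict(rule.to_dict())
        assert back.premise == rule.premise
        assert back.stats.table == rule.stats.table

    def test_text_syntax(self):
        rule = ir.Rule((EC("CD9", ">", 1), EC("CD13", "<", 3)), "no ETV6-RUNX1")
        assert str(rule) == "IF CD9 > 1 AND CD13 < 3 THEN no ETV6-RUNX1"
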