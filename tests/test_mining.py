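"""FP-Growth, rule generation, the temporal gap filter and rule scoring."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from habitmine.mining import (AssociationRule, BehaviorInstance, MinedHabit,
                              MiningConfig, PlantedHabit, Transaction,
                              attach_gaps, build_transactions, confidence,
                              evaluate_rules, fp_growth, generate_rules,
                              mine_habits, support, temporal_filter,
                              windows_to_behaviors)
from oracle import brute_force_frequent, brute_force_rules, random_database

D4 = [{"a", "b"}, {"a"}, {"a", "b", "c"}, {"b"}]


def t(hour, minute=0, day=1):
    return datetime(2024, 1, day, hour, minute)


def behavior(activity, start, minutes=10):
    return BehaviorInstance(activity, start, start + timedelta(minutes=minutes))


class TestBehaviors:
    def test_runs_collapse_to_instances(self):
        labels = ["A"] * 3 + ["B"] * 4
        ts = [t(8, i) for i in range(7)]
        out = windows_to_behaviors(labels, ts, min_run=3)
        assert [(b.activity, b.start_time, b.end_time) for b in out] == [
            ("A", t(8, 0), t(8, 2)), ("B", t(8, 3), t(8, 6))]

    def test_short_runs_dropped_and_neighbours_not_merged(self):
        labels = ["A", "A", "A", "B", "A", "A", "A"]
        ts = [t(8, i) for i in range(7)]
        out = windows_to_behaviors(labels, ts, min_run=3)
        assert [b.activity for b in out] == ["A", "A"]
        assert out[0].end_time < out[1].start_time

    def test_empty_input(self):
        assert windows_to_behaviors([], []) == []

    def test_time_bin_is_hour_of_start(self):
        assert behavior("wake", t(8, 5)).time_bin() == 8
        assert behavior("wake", t(8, 5)).time_bin(1800.0) == 16  # half-hour bins


class TestTransactions:
    def test_daily_scheme_items(self):
        """Waking at 08:05 and walking at 10:10 the same day become the
        itemset {(wake, 8), (walk, 10)}."""
        cfg = MiningConfig()
        txs = build_transactions(
            [behavior("wake", t(8, 5)), behavior("walk", t(10, 10))], cfg)
        assert len(txs) == 1
        assert txs[0].items == frozenset({("wake", 8), ("walk", 10)})

    def test_one_transaction_per_day(self):
        cfg = MiningConfig()
        txs = build_transactions(
            [behavior("wake", t(8, 5, day=1)), behavior("wake", t(8, 10, day=2))], cfg)
        assert len(txs) == 2

    def test_set_semantics_within_a_bin(self):
        cfg = MiningConfig()
        txs = build_transactions(
            [behavior("wake", t(8, 5)), behavior("wake", t(8, 40))], cfg)
        assert txs[0].items == frozenset({("wake", 8)})
        assert len(txs[0].occurrences[("wake", 8)]) == 2

    def test_other_label_excluded_by_default(self):
        cfg = MiningConfig()
        txs = build_transactions(
            [behavior("Other", t(8, 5)), behavior("wake", t(9, 0))], cfg)
        assert txs[0].items == frozenset({("wake", 9)})

    def test_ngram_scheme(self):
        cfg = MiningConfig(scheme="ngram", ngram_k=2)
        txs = build_transactions(
            [behavior("a", t(8)), behavior("b", t(9)), behavior("c", t(10))], cfg)
        assert len(txs) == 2


class TestSupportConfidence:
    def test_worked_example(self):
        assert support([("a"), ("b")], D4) == pytest.approx(0.5)
        assert support(["a", "b"], D4) == pytest.approx(0.5)
        assert confidence(["a"], ["b"], D4) == pytest.approx(2 / 3)

    def test_singleton_support_and_antimonotonicity(self):
        assert support(["a"], D4) == pytest.approx(0.75)
        assert support(["a", "b"], D4) <= support(["a"], D4)

    def test_empty_database_is_an_error(self):
        with pytest.raises(ValueError):
            support(["a"], [])

    def test_zero_antecedent_support_is_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            confidence(["zz"], ["a"], D4)


class TestFPGrowth:
    def test_toy_database_exact_itemsets(self):
        out = {fi.items: fi.support for fi in fp_growth(D4, 0.5)}
        assert out == {frozenset("a"): 0.75, frozenset("b"): 0.75,
                       frozenset("ab"): 0.5}

    def test_min_support_one_keeps_universal_itemsets_only(self):
        db = [{"a", "b"}, {"a", "b", "c"}, {"a", "b"}]
        out = {fi.items for fi in fp_growth(db, 1.0)}
        assert out == {frozenset("a"), frozenset("b"), frozenset("ab")}

    def test_invalid_min_support(self):
        with pytest.raises(ValueError):
            fp_growth(D4, 0.0)
        with pytest.raises(ValueError):
            fp_growth(D4, 1.5)

    def test_matches_bruteforce_oracle_on_random_databases(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            db = random_database(rng, int(rng.integers(2, 9)), int(rng.integers(5, 60)))
            ms = float(rng.choice([0.2, 0.4, 0.6, 0.8]))
            mined = {fi.items: fi.count for fi in fp_growth(db, ms)}
            assert mined == brute_force_frequent(db, ms)

    def test_antimonotonicity_of_reported_itemsets(self):
        rng = np.random.default_rng(3)
        db = random_database(rng, 7, 50)
        mined = {fi.items: fi.count for fi in fp_growth(db, 0.3)}
        for items, count in mined.items():
            for item in items:
                sub = items - {item}
                if sub:
                    assert sub in mined and mined[sub] >= count

    def test_canonical_output_order(self):
        out = fp_growth(D4, 0.4)
        keys = [(-fi.support, sorted(map(str, fi.items))) for fi in out]
        assert keys == sorted(keys)


class TestRuleGeneration:
    def test_rule_confidence_from_toy_database(self):
        freq = fp_growth(D4, 0.5)
        rules = generate_rules(freq, 0.6, len(D4))
        pairs = {(r.antecedent, r.consequent): r for r in rules}
        ab = pairs[(frozenset("a"), frozenset("b"))]
        assert ab.confidence == pytest.approx(2 / 3)
        assert ab.support == pytest.approx(0.5)
        assert generate_rules(freq, 0.7, len(D4)) == [
            r for r in generate_rules(freq, 0.0, len(D4)) if r.confidence >= 0.7]

    def test_zero_min_confidence_emits_all_candidates(self):
        freq = fp_growth(D4, 0.5)
        rules = generate_rules(freq, 0.0, len(D4))
        assert {(r.antecedent, r.consequent) for r in rules} == {
            (frozenset("a"), frozenset("b")), (frozenset("b"), frozenset("a"))}

    def test_singleton_itemsets_yield_no_rules(self):
        freq = fp_growth([{"a"}, {"a"}], 0.5)
        assert generate_rules(freq, 0.0, 2) == []

    def test_rules_match_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            db = random_database(rng, 6, 40)
            freq = fp_growth(db, 0.3)
            mined = {(r.antecedent, r.consequent): (r.support, r.confidence)
                     for r in generate_rules(freq, 0.5, len(db))}
            oracle = brute_force_rules(brute_force_frequent(db, 0.3), len(db), 0.5)
            assert mined == oracle

    def test_rule_invariants(self):
        with pytest.raises(ValueError):
            AssociationRule(frozenset("a"), frozenset("a"), 0.5, 0.5, 1)
        with pytest.raises(ValueError):
            AssociationRule(frozenset(), frozenset("a"), 0.5, 0.5, 1)


def _mined(rule_items, gaps_minutes):
    ant, cons = rule_items
    rule = AssociationRule(frozenset(ant), frozenset(cons), 0.9, 0.9, 9)
    gaps = [g * 60.0 for g in gaps_minutes]
    import statistics
    return MinedHabit(rule, gaps, statistics.median(abs(g) for g in gaps))


class TestTemporalFilter:
    def test_short_gap_rule_kept(self):
        habit = _mined(([("wake", 8)], [("toilet", 8)]), [4, 6, 5])
        result = temporal_filter([habit], max_gap_s=1800)
        assert result.kept == [habit] and result.removed == []

    def test_long_gap_rule_removed(self):
        habit = _mined(([("wake", 8)], [("dinner", 19)]), [11 * 60] * 5)
        result = temporal_filter([habit], max_gap_s=1800)
        assert result.kept == [] and result.removed == [habit]

    def test_infinite_threshold_is_identity(self):
        habits = [_mined(([("a", 1)], [("b", 2)]), [5]),
                  _mined(([("a", 1)], [("c", 20)]), [600])]
        result = temporal_filter(habits, max_gap_s=math.inf)
        assert result.kept == habits and result.removed == []

    def test_pure_filter_and_monotone_in_threshold(self):
        habits = [_mined(([("a", 1)], [("b", 2)]), [g]) for g in (1, 10, 100, 1000)]
        kept_sizes = [len(temporal_filter(habits, m * 60).kept)
                      for m in (0.5, 5, 50, 500, 5000)]
        assert kept_sizes == sorted(kept_sizes)
        for m in (0.5, 5, 50):
            assert set(map(id, temporal_filter(habits, m * 60).kept)) <= set(map(id, habits))

    def test_gap_computed_from_supporting_transactions(self):
        """Latest antecedent end to earliest consequent start, per day."""
        behaviors = [behavior("wake", t(8, 0), minutes=10),
                     behavior("toilet", t(8, 15), minutes=5)]
        txs = build_transactions(behaviors, MiningConfig())
        rule = AssociationRule(frozenset([("wake", 8)]), frozenset([("toilet", 8)]),
                               1.0, 1.0, 1)
        mined = attach_gaps([rule], txs)
        assert mined[0].gaps_s == [300.0]  # 08:10 -> 08:15

    def test_rule_without_support_is_dropped(self):
        txs = build_transactions([behavior("wake", t(8, 0))], MiningConfig())
        rule = AssociationRule(frozenset([("x", 1)]), frozenset([("y", 2)]), 0.1, 0.1, 0)
        assert attach_gaps([rule], txs) == []


class TestRuleEvaluation:
    PLANTED = [PlantedHabit(frozenset([("wake", 8)]), frozenset([("toilet", 8)]), 1800)]

    def test_precision_arithmetic(self):
        habits = [_mined(([("wake", 8)], [("toilet", 8)]), [5])] * 3 \
            + [_mined(([("tv", 20)], [("bed", 23)]), [10])]
        ev = evaluate_rules(habits, self.PLANTED)
        assert (ev.tp, ev.fp) == (3, 1)
        assert ev.precision == pytest.approx(0.75)

    def test_all_planted_gives_precision_one(self):
        habits = [_mined(([("wake", 8)], [("toilet", 8)]), [5])]
        assert evaluate_rules(habits, self.PLANTED).precision == pytest.approx(1.0)

    def test_planted_set_plus_one_decoy(self):
        planted = [PlantedHabit(frozenset([(f"a{i}", i)]), frozenset([(f"b{i}", i)]), 1800)
                   for i in range(5)]
        habits = [_mined(([(f"a{i}", i)], [(f"b{i}", i)]), [5]) for i in range(5)]
        habits.append(_mined(([("decoy", 1)], [("decoy2", 20)]), [5]))
        assert evaluate_rules(habits, planted).precision == pytest.approx(5 / 6)

    def test_gap_tolerance_enforced(self):
        too_slow = [_mined(([("wake", 8)], [("toilet", 8)]), [120])]
        assert evaluate_rules(too_slow, self.PLANTED).tp == 0

    def test_empty_habit_set_has_undefined_precision(self):
        assert evaluate_rules([], self.PLANTED).precision is None
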