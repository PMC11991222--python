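"""Temporal association-rule mining of classified behavior sequences.

The second half of the pipeline: classified windows are collapsed into
behavior instances, instances are grouped into timestamped transactions
(one per calendar day by default) whose items are ``(activity, hour-of-day
bin)`` pairs, frequent itemsets are mined with a from-scratch FP-Growth,
rules are generated by confidence, and a temporal filter discards rules
whose antecedent and consequent are separated by large time gaps — the
surviving rules are the habit set. Against a planted ground truth the
habit set is scored by precision = TP / (TP + FP).
"""

from __future__ import annotations

import json
import logging
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .casas import OTHER_LABEL

logger = logging.getLogger(__name__)

#: An item is a (activity, time-bin) pair.
Item = tuple[str, int]


@dataclass(frozen=True)
class BehaviorInstance:
    """One classified activity occurrence."""

    activity: str
    start_time: datetime
    end_time: datetime

    def __post_init__(self) -> None:
        if self.start_time > self.end_time:
            raise ValueError("start_time must be <= end_time")

    def time_bin(self, bin_width_s: float = 3600.0) -> int:
        """Discretised time of day of the start (default: hour 0..23)."""
        seconds = (self.start_time - self.start_time.replace(
            hour=0, minute=0, second=0, microsecond=0)).total_seconds()
        return int(seconds // bin_width_s)


@dataclass
class MiningConfig:
    """Thresholds and transaction-building parameters.

    ``min_support`` / ``min_confidence`` follow the usual fractional
    definitions; the experimental grid spans 0.75-0.85. ``max_gap_s`` is
    the temporal filter threshold on the median antecedent-to-consequent
    gap (default 30 minutes). ``time_bin_width_s`` sets the granularity of
    the time-of-day item component (default 1 hour). ``scheme`` is
    ``"daily"`` (one transaction per calendar day) or ``"ngram"``
    (sliding groups of ``ngram_k`` consecutive behaviors).
    """

    min_support: float = 0.8
    min_confidence: float = 0.8
    max_gap_s: float = 1800.0
    time_bin_width_s: float = 3600.0
    scheme: str = "daily"
    ngram_k: int = 5
    min_run: int = 3
    include_other: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValueError("min_support must be in (0, 1]")
        if not (0.0 < self.min_confidence <= 1.0):
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_gap_s <= 0:
            raise ValueError("max_gap must be positive")
        if self.scheme not in ("daily", "ngram"):
            raise ValueError(f"unknown transaction scheme {self.scheme!r}")


@dataclass
class Transaction:
    """A set of (activity, time-bin) items plus the behaviors behind them."""

    items: frozenset[Item]
    occurrences: dict[Item, list[BehaviorInstance]] = field(default_factory=dict)
    day: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("transaction items must be non-empty")


@dataclass
class AssociationRule:
    """X -> Y with its support and confidence."""

    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    support: float
    confidence: float
    support_count: int

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    def sort_key(self):
        return (-self.support, sorted(map(str, self.antecedent)),
                sorted(map(str, self.consequent)))


@dataclass
class MinedHabit:
    """A rule with the time gaps observed in its supporting transactions."""

    rule: AssociationRule
    gaps_s: list[float]           # signed: consequent start - antecedent end
    median_abs_gap_s: float

    def to_row(self) -> dict:
        fmt = lambda s: ";".join(f"{a}@{b}" for a, b in sorted(s))
        return {
            "antecedent": fmt(self.rule.antecedent),
            "consequent": fmt(self.rule.consequent),
            "support": round(self.rule.support, 6),
            "confidence": round(self.rule.confidence, 6),
            "median_abs_gap_s": round(self.median_abs_gap_s, 3),
        }


@dataclass
class HabitSet:
    """Result of the temporal filter: kept habits and removed rules."""

    kept: list[MinedHabit]
    removed: list[MinedHabit]
    max_gap_s: float

    def to_tsv(self, path) -> None:
        cols = ["antecedent", "consequent", "support", "confidence",
                "median_abs_gap_s", "kept"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for habit, kept in [(h, 1) for h in self.kept] + [(h, 0) for h in self.removed]:
                row = habit.to_row()
                row["kept"] = kept
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    def to_json(self, path) -> None:
        payload = {
            "max_gap_s": self.max_gap_s,
            "kept": [h.to_row() for h in self.kept],
            "removed": [h.to_row() for h in self.removed],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# behaviors and transactions


def windows_to_behaviors(
    labels: Sequence[str],
    end_timestamps: Sequence[datetime],
    *,
    min_run: int = 3,
) -> list[BehaviorInstance]:
    """Collapse consecutive identically-labelled windows into instances.

    Maximal runs of the same predicted label become one behavior spanning
    the run; runs shorter than ``min_run`` windows are discarded as
    classifier noise. Runs of the same label separated by a discarded run
    are *not* merged.
    """
    if len(labels) != len(end_timestamps):
        raise ValueError("labels and end_timestamps must have equal length")
    behaviors: list[BehaviorInstance] = []
    i, n = 0, len(labels)
    while i < n:
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if j - i + 1 >= min_run:
            behaviors.append(BehaviorInstance(labels[i], end_timestamps[i], end_timestamps[j]))
        i = j + 1
    return behaviors


def build_transactions(
    behaviors: Sequence[BehaviorInstance],
    cfg: MiningConfig,
) -> list[Transaction]:
    """Group time-ordered behaviors into timestamped transactions.

    Daily scheme: one transaction per calendar day, items are the day's
    ``(activity, time-bin)`` pairs (set semantics — repeats within a bin
    collapse). N-gram scheme: a sliding group of ``ngram_k`` consecutive
    behaviors per transaction.
    """
    kept = [b for b in behaviors
            if cfg.include_other or b.activity != OTHER_LABEL]

    def to_item(b: BehaviorInstance) -> Item:
        return (b.activity, b.time_bin(cfg.time_bin_width_s))

    groups: list[tuple[Optional[str], list[BehaviorInstance]]] = []
    if cfg.scheme == "daily":
        by_day: dict[str, list[BehaviorInstance]] = defaultdict(list)
        for b in kept:
            by_day[b.start_time.date().isoformat()].append(b)
        groups = sorted(by_day.items())
    else:
        k = cfg.ngram_k
        for i in range(max(0, len(kept) - k + 1)):
            groups.append((None, list(kept[i:i + k])))

    transactions = []
    for day, members in groups:
        occurrences: dict[Item, list[BehaviorInstance]] = defaultdict(list)
        for b in members:
            occurrences[to_item(b)].append(b)
        if occurrences:
            transactions.append(Transaction(frozenset(occurrences), dict(occurrences), day))
    return transactions


def _itemsets(transactions: Sequence) -> list[frozenset]:
    out = []
    for t in transactions:
        items = t.items if isinstance(t, Transaction) else frozenset(t)
        out.append(frozenset(items))
    return out


# ---------------------------------------------------------------------------
# support / confidence (the definitional operations)


def support(itemset: Iterable, transactions: Sequence) -> float:
    """Fraction of transactions containing every item of ``itemset``."""
    sets = _itemsets(transactions)
    if not sets:
        raise ValueError("empty transaction database")
    items = frozenset(itemset)
    return sum(items <= t for t in sets) / len(sets)


def confidence(antecedent: Iterable, consequent: Iterable, transactions: Sequence) -> float:
    """P(consequent | antecedent): |T(X u Y)| / |T(X)|.

    Raises ValueError when the antecedent never occurs (the conditional is
    undefined, never silently zero).
    """
    sets = _itemsets(transactions)
    if not sets:
        raise ValueError("empty transaction database")
    X, Y = frozenset(antecedent), frozenset(consequent)
    n_x = sum(X <= t for t in sets)
    if n_x == 0:
        raise ValueError("confidence undefined: antecedent occurs in no transaction")
    return sum((X | Y) <= t for t in sets) / n_x


# ---------------------------------------------------------------------------
# FP-Growth


class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}
        self.link: Optional[_FPNode] = None


class _FPTree:
    """Prefix tree of frequency-ordered transactions with header links."""

    def __init__(self):
        self.root = _FPNode(None, None)
        self.header: dict = {}   # item -> first node in the node-link chain
        self.counts: Counter = Counter()

    def insert(self, items: Sequence, count: int = 1) -> None:
        node = self.root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = _FPNode(item, node)
                node.children[item] = child
                child.link = self.header.get(item)
                self.header[item] = child
            child.count += count
            node = child
        for item in items:
            self.counts[item] += count

    def prefix_paths(self, item) -> list[tuple[list, int]]:
        """Conditional pattern base of ``item``: (path-to-root, count)."""
        paths = []
        node = self.header.get(item)
        while node is not None:
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            path.reverse()
            if path:
                paths.append((path, node.count))
            node = node.link
        return paths


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset
    count: int
    support: float


def _frequency_order(counts: Counter, n: int, min_support: float) -> dict:
    """item -> rank for items meeting the threshold; descending count,
    lexicographic (by string form) tie-break for determinism."""
    frequent = [i for i, c in counts.items() if c / n >= min_support]
    frequent.sort(key=lambda i: (-counts[i], str(i)))
    return {item: r for r, item in enumerate(frequent)}


def _mine(tree: _FPTree, suffix: frozenset, n: int, min_support: float,
          out: list[FrequentItemset]) -> None:
    # visit items in ascending frequency within this conditional tree
    items = sorted(tree.counts, key=lambda i: (tree.counts[i], str(i)))
    for item in items:
        count = tree.counts[item]
        if count / n < min_support:
            continue
        itemset = suffix | {item}
        out.append(FrequentItemset(frozenset(itemset), count, count / n))
        base = tree.prefix_paths(item)
        cond_counts: Counter = Counter()
        for path, c in base:
            for p in path:
                cond_counts[p] += c
        order = _frequency_order(cond_counts, n, min_support)
        cond_tree = _FPTree()
        for path, c in base:
            filtered = sorted((p for p in path if p in order), key=order.__getitem__)
            if filtered:
                cond_tree.insert(filtered, c)
        if cond_tree.counts:
            _mine(cond_tree, frozenset(itemset), n, min_support, out)


def fp_growth(transactions: Sequence, min_support: float) -> list[FrequentItemset]:
    """Mine all itemsets with support >= ``min_support`` via an FP-tree.

    Accepts :class:`Transaction` objects or plain item collections. Items
    are ordered by descending frequency within transactions, the tree is
    mined recursively through conditional pattern bases, and no candidate
    sets are generated. Output is canonically ordered (support descending,
    then lexicographic), so runs are diffable.
    """
    if not (0.0 < min_support <= 1.0):
        raise ValueError("min_support must be in (0, 1]")
    sets = _itemsets(transactions)
    if not sets:
        raise ValueError("empty transaction database")
    n = len(sets)
    counts: Counter = Counter()
    for t in sets:
        counts.update(t)
    order = _frequency_order(counts, n, min_support)
    tree = _FPTree()
    for t in sets:
        filtered = sorted((i for i in t if i in order), key=order.__getitem__)
        if filtered:
            tree.insert(filtered)
    out: list[FrequentItemset] = []
    _mine(tree, frozenset(), n, min_support, out)
    out.sort(key=lambda fi: (-fi.support, sorted(map(str, fi.items))))
    return out


def generate_rules(
    frequent_itemsets: Sequence[FrequentItemset],
    min_confidence: float,
    n_transactions: int,
) -> list[AssociationRule]:
    """Emit X -> Z\\X for every frequent Z and non-empty proper subset X
    with confidence >= ``min_confidence``.

    Anti-monotonicity guarantees every subset's count is available.
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError("min_confidence must be in [0, 1]")
    count_of = {fi.items: fi.count for fi in frequent_itemsets}
    rules = []
    for fi in frequent_itemsets:
        if len(fi.items) < 2:
            continue
        members = sorted(fi.items, key=str)
        for r in range(1, len(members)):
            for X in combinations(members, r):
                X = frozenset(X)
                conf = fi.count / count_of[X]
                if conf >= min_confidence:
                    rules.append(AssociationRule(
                        X, fi.items - X, fi.count / n_transactions, conf, fi.count))
    rules.sort(key=AssociationRule.sort_key)
    return rules


# ---------------------------------------------------------------------------
# temporal filter and evaluation


def _rule_gaps(rule: AssociationRule, transactions: Sequence[Transaction]) -> list[float]:
    """Signed gap (s) per supporting transaction: earliest consequent start
    minus latest antecedent end."""
    gaps = []
    full = rule.antecedent | rule.consequent
    for t in transactions:
        if not full <= t.items:
            continue
        ant_end = max(b.end_time for i in rule.antecedent for b in t.occurrences[i])
        cons_start = min(b.start_time for i in rule.consequent for b in t.occurrences[i])
        gaps.append((cons_start - ant_end).total_seconds())
    return gaps


def attach_gaps(rules: Sequence[AssociationRule],
                transactions: Sequence[Transaction]) -> list[MinedHabit]:
    """Compute each rule's observed time-gap distribution."""
    mined = []
    for rule in rules:
        gaps = _rule_gaps(rule, transactions)
        if not gaps:
            logger.warning("rule %s -> %s has no supporting occurrences; dropped",
                           set(rule.antecedent), set(rule.consequent))
            continue
        mined.append(MinedHabit(rule, gaps, statistics.median(abs(g) for g in gaps)))
    return mined


def temporal_filter(mined: Sequence[MinedHabit], max_gap_s: float) -> HabitSet:
    """Keep rules whose median absolute antecedent-to-consequent gap is
    within ``max_gap_s``; the kept rules are the habit set. A pure filter:
    output is a subset of input and monotone in the threshold."""
    if max_gap_s <= 0:
        raise ValueError("max_gap must be positive")
    kept, removed = [], []
    for habit in mined:
        (kept if habit.median_abs_gap_s <= max_gap_s else removed).append(habit)
    return HabitSet(kept, removed, max_gap_s)


@dataclass(frozen=True)
class PlantedHabit:
    """Ground-truth habit: item-level antecedent/consequent + gap tolerance."""

    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    gap_tolerance_s: float


@dataclass
class RuleEvaluation:
    tp: int
    fp: int
    matched: list[MinedHabit]

    @property
    def precision(self) -> Optional[float]:
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)


def is_true_positive(habit: MinedHabit, truth: Sequence[PlantedHabit],
                     *, match: str = "exact") -> bool:
    for planted in truth:
        if match == "exact":
            hit = (habit.rule.antecedent == planted.antecedent
                   and habit.rule.consequent == planted.consequent)
        else:  # "subset": planted pair contained in the mined rule
            hit = (planted.antecedent <= habit.rule.antecedent
                   and planted.consequent <= habit.rule.consequent)
        if hit and habit.median_abs_gap_s <= planted.gap_tolerance_s:
            return True
    return False


def evaluate_rules(habits: Sequence[MinedHabit], truth: Sequence[PlantedHabit],
                   *, match: str = "exact") -> RuleEvaluation:
    """Score mined habits against the planted ground truth (precision =
    TP / (TP + FP)); precision is None (undefined) for an empty habit set."""
    tp, fp, matched = 0, 0, []
    for habit in habits:
        if is_true_positive(habit, truth, match=match):
            tp += 1
            matched.append(habit)
        else:
            fp += 1
    return RuleEvaluation(tp, fp, matched)


def mine_habits(transactions: Sequence[Transaction], cfg: MiningConfig
                ) -> tuple[list[MinedHabit], HabitSet]:
    """Frequent itemsets -> rules -> gaps -> temporal filter, in one call.

    Returns (all rules with gaps, filtered habit set).
    """
    itemsets = fp_growth(transactions, cfg.min_support)
    rules = generate_rules(itemsets, cfg.min_confidence, len(transactions))
    mined = attach_gaps(rules, transactions)
    return mined, temporal_filter(mined, cfg.max_gap_s)
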