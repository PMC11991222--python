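"""Brute-force association-rule oracle for tests.

Exhaustively enumerates the itemset lattice with bitmask subset tests —
independent of the FP-tree code path it cross-checks. Only usable for
small item universes (<= ~15 items).
"""

from __future__ import annotations

from itertools import combinations


def brute_force_frequent(transactions, min_support: float) -> dict[frozenset, int]:
    """All itemsets with support >= min_support, via lattice enumeration."""
    sets = [frozenset(t) for t in transactions]
    items = sorted({i for t in sets for i in t}, key=str)
    bit = {item: 1 << k for k, item in enumerate(items)}
    masks = [sum(bit[i] for i in t) for t in sets]
    n = len(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            m = sum(bit[i] for i in combo)
            count = sum((tm & m) == m for tm in masks)
            if count / n >= min_support:
                out[frozenset(combo)] = count
    return out


def brute_force_rules(
    frequent: dict[frozenset, int], n_transactions: int, min_confidence: float
) -> dict[tuple[frozenset, frozenset], tuple[float, float]]:
    """(antecedent, consequent) -> (support, confidence) for confident rules."""
    rules = {}
    for Z, count in frequent.items():
        if len(Z) < 2:
            continue
        members = sorted(Z, key=str)
        for r in range(1, len(members)):
            for X in combinations(members, r):
                X = frozenset(X)
                conf = count / frequent[X]
                if conf >= min_confidence:
                    rules[(X, Z - X)] = (count / n_transactions, conf)
    return rules


def random_database(rng, n_items: int, n_transactions: int) -> list[frozenset]:
    """A random transaction database over string items a..j."""
    items = [chr(ord("a") + i) for i in range(n_items)]
    db = []
    for _ in range(n_transactions):
        # skewed inclusion probabilities so some itemsets clear high thresholds
        probs = rng.uniform(0.1, 0.95, size=n_items)
        t = frozenset(i for i, p in zip(items, probs) if rng.random() < p)
        if t:
            db.append(t)
    if not db:
        db.append(frozenset(items[:1]))
    return db
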