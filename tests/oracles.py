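"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive (exact rational arithmetic,
exhaustive pair counting) and shares no code with the implementations it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_upper_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for the 2x2 table by exhaustive enumeration, exact rational.

    X is the top-left cell with all margins fixed: row1 = a+b draws from a
    population of N = a+b+c+d with a+c successes.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, row1)
    total = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        if row1 - k > n - col1:
            continue
        total += Fraction(comb(col1, k) * comb(n - col1, row1 - k), denom)
    return total


def auc_pair_counting(scores, labels) -> float:
    """AUC by exhaustive comparison of every positive-negative pair."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ari_pair_counting(labels_a, labels_b) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    n = len(labels_a)
    groups_a: dict = {}
    groups_b: dict = {}
    for i, (la, lb) in enumerate(zip(labels_a, labels_b)):
        groups_a.setdefault(la, set()).add(i)
        groups_b.setdefault(lb, set()).add(i)
    sum_ij = sum(
        comb(len(sa & sb), 2) for sa in groups_a.values() for sb in groups_b.values()
    )
    sum_a = sum(comb(len(s), 2) for s in groups_a.values())
    sum_b = sum(comb(len(s), 2) for s in groups_b.values())
    pairs = comb(n, 2)
    expected = sum_a * sum_b / pairs
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def pearson_by_hand(xs, ys) -> float:
    """Textbook Pearson correlation via explicit summation."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    dx = sum((x - mx) ** 2 for x in xs) ** 0.5
    dy = sum((y - my) ** 2 for y in ys) ** 0.5
    return num / (dx * dy)


def find_all_synonym_spans(text: str, synonyms: dict[str, str]):
    """All boundary-valid (start, end, entity) placements, by brute scan.

    ``synonyms`` maps surface form -> entity id; matching is
    case-insensitive and requires non-alphanumeric flanks.
    """
    low = text.lower()
    out = []
    for syn, entity in synonyms.items():
        s = syn.lower()
        start = 0
        while True:
            i = low.find(s, start)
            if i < 0:
                break
            j = i + len(s)
            left_ok = i == 0 or not low[i - 1].isalnum()
            right_ok = j == len(low) or not low[j].isalnum()
            if left_ok and right_ok:
                out.append((i, j, entity))
            start = i + 1
    return sorted(out)


def resolve_longest_leftmost(spans):
    """Greedy leftmost/longest-first resolution of overlapping spans."""
    chosen = []
    for start, end, entity in sorted(spans, key=lambda t: (t[0], -(t[1] - t[0]))):
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, entity))
    return sorted(chosen)
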