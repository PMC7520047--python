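"""Ranked-list comparison: rank-biased overlap (RBO) and top-k overlap.

RBO compares two indefinite rankings as a weighted average of their overlap
fractions at every depth d, with geometric weights (1-p)·p^(d-1).  The
persistence parameter p controls how top-weighted the measure is; p = 0.9
places about 86% of the total weight on the first ten ranks.  The
extrapolated variant (RBO_EXT) assumes the agreement seen at the end of the
shorter list continues, giving a point estimate in [0, 1] for lists of
unequal length.

Reference: Webber, Moffat & Zobel (2010), "A similarity measure for
indefinite rankings".
"""

from __future__ import annotations

import math
from typing import Sequence


def _validate_ranked(items: Sequence, name: str) -> list:
    items = list(items)
    if len(set(items)) != len(items):
        raise ValueError(f"ranked list {name} contains duplicates")
    return items


def rbo(list_a: Sequence, list_b: Sequence, p: float = 0.9, depth: int | None = None) -> float:
    """Rank-biased overlap of two duplicate-free ranked lists.

    With ``depth=None`` (default) the extrapolated RBO_EXT is returned;
    a finite ``depth`` truncates the weighted sum at that depth instead
    (a lower bound that ignores all deeper agreement).  Symmetric in its
    arguments.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"persistence parameter p must be in (0, 1), got {p}")
    a = _validate_ranked(list_a, "a")
    b = _validate_ranked(list_b, "b")
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    s, l = len(short), len(long_)

    seen_s: set = set()
    seen_l: set = set()
    overlap = 0
    X = []  # X[d-1] = overlap at depth d, for d = 1..l
    for d in range(1, l + 1):
        if d <= s:
            item = short[d - 1]
            if item in seen_l:
                overlap += 1
            seen_s.add(item)
        item = long_[d - 1]
        if item in seen_s and item not in seen_l:
            overlap += 1
        seen_l.add(item)
        X.append(overlap)

    if depth is not None:
        if depth < 1:
            raise ValueError("depth must be >= 1")
        total = 0.0
        for d in range(1, depth + 1):
            x = X[min(d, l) - 1]
            total += (1 - p) * p ** (d - 1) * (x / d)
        return total

    X_s, X_l = X[s - 1], X[l - 1]
    sum1 = sum((X[d - 1] / d) * p**d for d in range(1, l + 1))
    sum2 = sum((X_s * (d - s)) / (s * d) * p**d for d in range(s + 1, l + 1))
    tail = ((X_l - X_s) / l + X_s / s) * p**l
    return (1 - p) / p * (sum1 + sum2) + tail


def rbo_weight(p: float, d: int) -> float:
    """Fraction of total RBO weight carried by ranks 1..d.

    Closed form:  W(1:d) = 1 - p^(d-1)
                         + d·((1-p)/p)·(ln(1/(1-p)) - Σ_{i=1}^{d-1} p^i / i)
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"persistence parameter p must be in (0, 1), got {p}")
    if d < 1:
        raise ValueError("d must be >= 1")
    partial = sum(p**i / i for i in range(1, d))
    return 1.0 - p ** (d - 1) + d * ((1 - p) / p) * (math.log(1.0 / (1.0 - p)) - partial)


def top_k_overlap(list_a: Sequence, list_b: Sequence, k: int) -> int:
    """Size of the intersection of the two top-k prefixes (set semantics)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    a = _validate_ranked(list_a, "a")
    b = _validate_ranked(list_b, "b")
    return len(set(a[:k]) & set(b[:k]))
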