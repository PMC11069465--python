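"""Brute-force reference solver for the all-hits mapping problem.

Enumerates every window t[a, b] of the text sketch, evaluates the
threshold, the left/right occurrence (reasonability) conditions, and
maximality quantified over ALL containing windows - a literal reading of
the problem definition with no dynamic-programming shortcuts. O(|t|^2)
windows with O(|t|^2) total counting work and an O(|t|^4)-ish maximality
pass: test-scale only, and the arbiter for the streaming algorithm.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .mapping import FinalMapping
from .score import SCORE_EPS, ScoringScheme
from .sketch import OccurrenceProfile, Sketch, count_occurrences

__all__ = ["brute_force_shared_count", "brute_force_final_mappings"]


def brute_force_shared_count(
    t: Sketch, a: int, b: int, p_counts: OccurrenceProfile
) -> int:
    """Naive sum_x min(occ(x, p), occ(x, t[a, b]))."""
    if not 0 <= a <= b < len(t):
        raise ValueError(f"window [{a}, {b}] out of bounds for |t|={len(t)}")
    window = Counter(t.kmers[a : b + 1])
    return sum(min(n, p_counts[x]) for x, n in window.items())


def brute_force_final_mappings(
    t: Sketch,
    p: Sketch,
    scheme: ScoringScheme | None = None,
    thr: float | None = None,
) -> list[FinalMapping]:
    """All final mappings by exhaustive enumeration, sorted by (a, b)."""
    if scheme is None:
        scheme = ScoringScheme()
    if len(p) == 0:
        raise ValueError("pattern sketch must be non-empty")
    p_counts = count_occurrences(p)
    p_len = len(p)
    if thr is None:
        thr = scheme.threshold(p_len)
    n = len(t)
    if n == 0:
        return []

    # shared counts and reasonability flags for every window, incrementally
    counts = np.zeros((n, n), dtype=np.int64)
    scores = np.full((n, n), -np.inf)
    left_ok = np.zeros((n, n), dtype=bool)
    right_ok = np.zeros((n, n), dtype=bool)
    for a in range(n):
        window: Counter = Counter()
        m = 0
        for b in range(a, n):
            x = t.kmers[b]
            window[x] += 1
            if window[x] <= p_counts[x]:
                m += 1
            counts[a, b] = m
            scores[a, b] = scheme.score_from_count(m, b - a + 1, p_len)
            left_ok[a, b] = window[t.kmers[a]] <= p_counts[t.kmers[a]]
            right_ok[a, b] = window[x] <= p_counts[x]

    out = []
    for a in range(n):
        for b in range(a, n):
            sc = scores[a, b]
            if sc < thr - SCORE_EPS or not (left_ok[a, b] and right_ok[a, b]):
                continue
            # maximal: no containing window of strictly greater score
            if (scores[: a + 1, b:] > sc).any():
                continue
            out.append(
                FinalMapping(
                    i=-1, j=-1, a=a, b=b,
                    count=int(counts[a, b]), score=float(sc), threshold=thr,
                )
            )
    return out
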