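"""Multiset similarity scores over sketch pairs and their equivalences.

For a k-mer x and sketches p (pattern) and s (a candidate window of the
text sketch), let

    x_min  = min(occ(x, p), occ(x, s))
    x_max  = max(occ(x, p), occ(x, s))
    x_diff = x_max - x_min

so that |s| + |p| = sum_x (2 x_min + x_diff). The two scores used for
mapping are the weighted Jaccard

    sc_j(s, p) = sum_x x_min / sum_x x_max

and the linear score with tuning weight w > 0

    sc_l(s, p; w) = sum_x (x_min - w x_diff)
                  = (1 + 2w) sum_x x_min - w (|s| + |p|).

sc_l strictly dominates sc_j: any weighted-Jaccard cutoff t can be
rewritten as a linear scheme (w = t/(1-t), cutoff 0) accepting exactly
the same windows, while no Jaccard cutoff can reproduce every linear
separation. Four natural variants (sc_A..sc_D, re-weighting x_min,
x_diff, x_max or |s|) are all affine transforms of sc_l and hence
pairwise equivalent; `variant_to_linear` gives the explicit maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .sketch import OccurrenceProfile

__all__ = [
    "LinearScoreParams",
    "VariantScoreParams",
    "ScoringScheme",
    "shared_count",
    "weighted_jaccard",
    "linear_score",
    "variant_score",
    "jaccard_threshold_to_linear",
    "variant_to_linear",
]

#: absolute tolerance applied to >= threshold comparisons on float scores
SCORE_EPS = 1e-9


@dataclass(frozen=True)
class LinearScoreParams:
    """Weight w > 0 trading a shared occurrence against a non-shared one."""

    w: float = 1.0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"linear score weight w must be > 0, got {self.w}")


@dataclass(frozen=True)
class VariantScoreParams:
    """One of the four re-parameterized linear-family scores.

    variant A: sum(a1 * x_min - x_diff),        a1 > 0
    variant B: sum(b1 * x_min - b2 * x_diff),   b1 > 0, b2 > 0
    variant C: sum(c1 * x_min - c2 * x_max),    c1 > c2 > 0
    variant D: sum(d1 * x_min) - d2 * |s|,      d1 > 2*d2, d2 > 0
    """

    variant: str
    params: tuple

    def __post_init__(self) -> None:
        v, pr = self.variant, self.params
        ok = {
            "A": lambda a1: a1 > 0,
            "B": lambda b1, b2: b1 > 0 and b2 > 0,
            "C": lambda c1, c2: c1 > c2 > 0,
            "D": lambda d1, d2: d1 > 2 * d2 and d2 > 0,
        }
        if v not in ok:
            raise ValueError(f"unknown score variant {v!r}")
        if not ok[v](*pr):
            raise ValueError(f"parameters {pr} violate the constraints of variant {v}")


def shared_count(p_counts: OccurrenceProfile, s_counts: OccurrenceProfile) -> int:
    """sum_x x_min: size of the multiset intersection of the two sketches."""
    a, b = p_counts, s_counts
    if len(b.counts) < len(a.counts):
        a, b = b, a
    return sum(min(n, b[x]) for x, n in a.counts.items())


def _diff_sum(p_counts: OccurrenceProfile, s_counts: OccurrenceProfile) -> int:
    # sum_x x_diff = |s| + |p| - 2 * sum_x x_min
    return p_counts.total + s_counts.total - 2 * shared_count(p_counts, s_counts)


def weighted_jaccard(p_counts: OccurrenceProfile, s_counts: OccurrenceProfile) -> float:
    """sum x_min / sum x_max; 1 iff permutations, 0 iff disjoint."""
    if p_counts.total == 0 and s_counts.total == 0:
        raise ValueError("weighted Jaccard is undefined for two empty sketches")
    m = shared_count(p_counts, s_counts)
    return m / (p_counts.total + s_counts.total - m)


def linear_score(
    p_counts: OccurrenceProfile,
    s_counts: OccurrenceProfile,
    params: LinearScoreParams | float = LinearScoreParams(),
) -> float:
    """sc_l = (1 + 2w) * sum x_min - w * (|s| + |p|)."""
    w = params.w if isinstance(params, LinearScoreParams) else LinearScoreParams(params).w
    m = shared_count(p_counts, s_counts)
    return (1 + 2 * w) * m - w * (p_counts.total + s_counts.total)


def variant_score(
    p_counts: OccurrenceProfile,
    s_counts: OccurrenceProfile,
    params: VariantScoreParams,
    s_len: int | None = None,
    p_len: int | None = None,
) -> float:
    """Evaluate one of sc_A..sc_D exactly from the occurrence profiles.

    ``s_len``/``p_len`` default to the profile totals; variant D is the
    only one that references |s| (the window length) directly.
    """
    if s_len is None:
        s_len = s_counts.total
    if p_len is None:
        p_len = p_counts.total
    m = shared_count(p_counts, s_counts)
    d = p_len + s_len - 2 * m  # sum_x x_diff
    v, pr = params.variant, params.params
    if v == "A":
        return pr[0] * m - d
    if v == "B":
        return pr[0] * m - pr[1] * d
    if v == "C":
        return pr[0] * m - pr[1] * (m + d)  # x_max = x_min + x_diff
    return pr[0] * m - pr[1] * s_len  # D


def jaccard_threshold_to_linear(
    t: float, p_len: int, default_w: float = 1.0
) -> tuple[LinearScoreParams, float]:
    """Linear scheme accepting exactly the windows a Jaccard cutoff t does.

    0 < t < 1: w = t / (1 - t), cutoff 0. t = 0: Jaccard accepts every
    window, so the cutoff is -inf (any w > 0). t = 1: only permutations
    of p reach Jaccard 1, and they alone attain sc_l = |p|, so cutoff
    |p|. t > 1: unattainable; cutoff |p| + 1 rejects everything.
    """
    if t < 0:
        raise ValueError(f"jaccard threshold must be >= 0, got {t}")
    if t == 0:
        return LinearScoreParams(default_w), float("-inf")
    if t < 1:
        return LinearScoreParams(t / (1 - t)), 0.0
    if t == 1:
        return LinearScoreParams(default_w), float(p_len)
    return LinearScoreParams(default_w), float(p_len + 1)


def variant_to_linear(
    params: VariantScoreParams,
) -> tuple[LinearScoreParams, float, Callable[[int], float]]:
    """(w, scale, offset) with variant = scale * sc_l(.; w) + offset(|p|).

    Derivation uses x_max = x_min + x_diff and
    |s| = 2 sum x_min + sum x_diff - |p|; the positive scale and the
    |p|-only offset preserve threshold separations, which is what makes
    all four variants equivalent to sc_l.
    """
    v, pr = params.variant, params.params
    if v == "A":
        a1 = pr[0]
        return LinearScoreParams(1 / a1), a1, lambda p_len: 0.0
    if v == "B":
        b1, b2 = pr
        return LinearScoreParams(b2 / b1), b1, lambda p_len: 0.0
    if v == "C":
        c1, c2 = pr
        return LinearScoreParams(c2 / (c1 - c2)), c1 - c2, lambda p_len: 0.0
    d1, d2 = pr
    return (
        LinearScoreParams(d2 / (d1 - 2 * d2)),
        d1 - 2 * d2,
        lambda p_len: d2 * p_len,
    )


@dataclass
class ScoringScheme:
    """A score function plus a threshold rule thr(|p|).

    ``kind`` is ``"linear"`` (with weight ``w``) or ``"jaccard"``.
    ``thr`` is either a constant or a callable of the pattern-sketch
    length. Scores of text windows are derived from the DP's integer
    shared count at read-out, so the scheme only needs the window and
    pattern lengths alongside that count.
    """

    kind: str = "linear"
    w: float = 1.0
    thr: float | Callable[[int], float] = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "jaccard"):
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.kind == "linear":
            LinearScoreParams(self.w)  # validate

    def score_from_count(self, count: int, s_len: int, p_len: int) -> float:
        """Score of a window with ``count`` shared occurrences and length
        ``s_len`` (both in sketch positions) against a pattern of length
        ``p_len``."""
        if self.kind == "linear":
            return (1 + 2 * self.w) * count - self.w * (s_len + p_len)
        return count / (s_len + p_len - count)

    def score(self, p_counts: OccurrenceProfile, s_counts: OccurrenceProfile) -> float:
        if self.kind == "linear":
            return linear_score(p_counts, s_counts, LinearScoreParams(self.w))
        return weighted_jaccard(p_counts, s_counts)

    def threshold(self, p_len: int) -> float:
        return self.thr(p_len) if callable(self.thr) else float(self.thr)

    @classmethod
    def from_jaccard_threshold(cls, t: float, p_len: int) -> "ScoringScheme":
        """Linear scheme equivalent to a weighted-Jaccard scheme with cutoff t."""
        params, cutoff = jaccard_threshold_to_linear(t, p_len)
        return cls(kind="linear", w=params.w, thr=cutoff)
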