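"""Exact all-hits mapping between a pattern sketch and a text sketch.

Given a pattern sketch p (the read) and a text sketch t (the reference),
a *candidate mapping* is any window t[a, b]. A window is *reasonable* if
its first and last k-mers occur in it no more often than in the pattern
(so it starts and ends with k-mers that genuinely match), *maximal* if no
containing window scores strictly higher, and *final* if it is
reasonable, maximal and scores at least the threshold. The task is to
report every final mapping.

Only windows whose endpoints carry pattern k-mers can be reasonable, so
let L be the increasing list of positions of t holding a k-mer of p and
ell = |L|. The dynamic program fills, right to left, the matrix

    S(i, j) = sum_x min(occ(x, p), occ(x, t[L[i], L[j]]))

using the recurrence S(i, j) = S(i, j+1) - [occ(t[L[j+1]], t[L[i], L[j+1]])
<= occ(t[L[j+1]], p)], with two hash tables of pattern-k-mer counts
(P_cnt for p, T_cnt for the running prefix of t) and counters c1, c2
providing the occurrence test in constant time. Either score is derived
from the integer S(i, j) at read-out in O(1). Only two columns are held
in memory; the full run costs O(|t| + |p| + ell^2) time.

The right-to-left, top-to-bottom traversal visits every window containing
t[L[i], L[j]] before visiting it, so maximality is decided on the fly
against a per-start-row prefix maximum over all previously traversed
cell scores. Trimming non-pattern k-mers off a window's ends can only
raise its score, hence the best containing *cell* dominates the best
containing *interval* and the streamed check is exactly the maximality of
the problem definition (strictly greater score suppresses; equal-score
nested mappings are all reported).

Two column engines are provided: the scalar reference operations
(`init_last_column` / `advance_column`, written to mirror the recurrence
cell by cell) and a numpy-vectorized engine used by `find_mappings`;
tests hold them equal on random instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .score import SCORE_EPS, ScoringScheme
from .sketch import OccurrenceProfile, Sketch, count_occurrences

__all__ = [
    "SharedPositions",
    "DPColumn",
    "FinalMapping",
    "build_shared_positions",
    "init_last_column",
    "advance_column",
    "score_from_count",
    "collect_final_mappings",
    "find_mappings",
]


@dataclass
class SharedPositions:
    """Positions of the text sketch carrying pattern k-mers."""

    L: np.ndarray
    ell: int


@dataclass
class DPColumn:
    """One column j of S: shared counts of the windows t[L[i], L[j]] for
    rows 0..j, plus the smallest right-reasonable row index i_star
    (-1 while not yet resolved)."""

    j: int
    values: np.ndarray
    i_star: int


@dataclass
class FinalMapping:
    """A reported window t[L[i], L[j]] = t[a, b] with its score.

    ``start``/``end`` give the 0-based half-open base-coordinate span
    [offset(a), offset(b) + k) when the text sketch carries offsets.
    """

    i: int
    j: int
    a: int
    b: int
    count: int
    score: float
    threshold: float
    ref_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"

    def key(self) -> tuple:
        return (self.a, self.b, round(self.score, 9))


def build_shared_positions(t: Sketch, p_counts: OccurrenceProfile) -> SharedPositions:
    """Scan t once for positions whose k-mer occurs in the pattern."""
    L = np.fromiter(
        (i for i, x in enumerate(t.kmers) if x in p_counts),
        dtype=np.int64,
    )
    return SharedPositions(L, len(L))


# ---------------------------------------------------------------------------
# scalar reference engine

def init_last_column(
    t_kmers, L: np.ndarray, p_counts: OccurrenceProfile
) -> tuple[DPColumn, dict]:
    """Bottom-up base case j = ell - 1, initializing T_cnt on the way.

    Walking i from ell-1 down to 0, T_cnt accumulates occ(x, t[L[i],
    L[ell-1]]); the cell gains +1 over the one below exactly when the
    entering k-mer t[L[i]] still fits inside the pattern's budget, and
    the window is right-reasonable while the last k-mer's running count
    stays within its pattern count. On return T_cnt holds the counts over
    the full span t[L[0], L[ell-1]].
    """
    ell = len(L)
    if ell < 1:
        raise ValueError("init_last_column requires at least one shared position")
    values = np.zeros(ell, dtype=np.int64)
    T_cnt: dict = {}
    y = t_kmers[L[ell - 1]]
    values[ell - 1] = 1
    T_cnt[y] = 1
    i_star = ell - 1
    p_y = p_counts[y]
    for i in range(ell - 2, -1, -1):
        x = t_kmers[L[i]]
        T_cnt[x] = T_cnt.get(x, 0) + 1
        if T_cnt[x] <= p_counts[x]:
            values[i] = values[i + 1] + 1
        else:
            values[i] = values[i + 1]
        if T_cnt[y] <= p_y:
            i_star = i
    return DPColumn(ell - 1, values, i_star), T_cnt


def advance_column(
    col_next: DPColumn,
    t_kmers,
    L: np.ndarray,
    p_counts: OccurrenceProfile,
    T_cnt: dict,
) -> tuple[DPColumn, int]:
    """Derive column j = col_next.j - 1 from column j+1 (the recurrence).

    The leaving k-mer is x = t[L[j+1]]; occ(x, t[L[i], L[j+1]]) is
    c2 - c1 with c2 = T_cnt[x] (the prefix count up to L[j+1], the entry
    invariant) and c1 the occurrences of x before row i, accumulated as
    the rows are walked. The subtract-1 case is taken exactly for the
    right-reasonable cells of column j+1, so the smallest such row is
    returned as i_star of column j+1 (the diagonal cell is always
    right-reasonable). On exit T_cnt is decremented to the column-j
    invariant.

    Column j's own i_star is discovered one step later, when advancing to
    j-1; the returned DPColumn carries a -1 placeholder until then.
    """
    j1 = col_next.j
    if j1 < 1:
        raise ValueError("cannot advance left of column 0")
    x = t_kmers[L[j1]]
    c2 = T_cnt[x]
    p_x = p_counts[x]
    values = np.empty(j1, dtype=np.int64)
    i_star_next = j1  # diagonal fallback
    found = False
    c1 = 0
    prev = col_next.values
    for i in range(j1):
        if c2 - c1 <= p_x:
            values[i] = prev[i] - 1
            if not found:
                i_star_next = i
                found = True
        else:
            values[i] = prev[i]
        if t_kmers[L[i]] == x:
            c1 += 1
    T_cnt[x] = c2 - 1
    return DPColumn(j1 - 1, values, -1), i_star_next


def _columns_reference(t_kmers, L, p_counts):
    """Stream columns (last first) with i_star resolved, scalar engine."""
    col, _T_cnt = init_last_column(t_kmers, L, p_counts)
    while col.j > 0:
        nxt, i_star = advance_column(col, t_kmers, L, p_counts, _T_cnt)
        assert col.i_star in (-1, i_star), "i_star bookkeeping diverged"
        col.i_star = i_star
        yield col
        col = nxt
    col.i_star = 0  # single diagonal cell, always reasonable
    yield col


# ---------------------------------------------------------------------------
# vectorized engine

def _columns_fast(t_kmers, L, p_counts):
    """Same column stream as `_columns_reference`, one numpy pass per
    column: pattern k-mers are re-encoded as small integer ids, so the
    c1 prefix counts and the recurrence's case test become array ops."""
    ell = len(L)
    ids = {x: i for i, x in enumerate(p_counts.counts)}
    tl = np.fromiter((ids[t_kmers[i]] for i in L), dtype=np.int64, count=ell)
    p_cnt = np.zeros(len(ids), dtype=np.int64)
    for x, c in p_counts.counts.items():
        p_cnt[ids[x]] = c

    # last column: suffix occurrence rank of each position's k-mer
    suffix_rank = np.empty(ell, dtype=np.int64)
    order = np.argsort(tl, kind="stable")
    sorted_ids = tl[order]
    starts = np.flatnonzero(np.concatenate(([True], sorted_ids[1:] != sorted_ids[:-1])))
    group_len = np.diff(np.concatenate((starts, [ell])))
    within = np.arange(ell) - np.repeat(starts, group_len)
    suffix_rank[order] = np.repeat(group_len, group_len) - within
    inc = suffix_rank <= p_cnt[tl]
    values = inc[::-1].cumsum()[::-1].astype(np.int64)
    y = tl[ell - 1]
    sy = (tl == y)[::-1].cumsum()[::-1]
    right_ok = sy <= p_cnt[y]
    i_star_last = int(np.argmax(right_ok)) if right_ok.any() else ell - 1

    T_cnt = np.bincount(tl, minlength=len(ids))
    col = DPColumn(ell - 1, values, i_star_last)
    while col.j > 0:
        j1 = col.j
        x = tl[j1]
        c2 = T_cnt[x]
        c1 = np.concatenate(([0], np.cumsum(tl[:j1] == x)[:-1])) if j1 > 1 else np.zeros(1, dtype=np.int64)
        cond = (c2 - c1) <= p_cnt[x]
        i_star = int(np.argmax(cond)) if cond.any() else j1
        assert col.i_star in (-1, i_star), "i_star bookkeeping diverged"
        col.i_star = i_star
        yield col
        T_cnt[x] -= 1
        col = DPColumn(j1 - 1, col.values[:j1] - cond, -1)
    col.i_star = 0
    yield col


def score_from_count(
    count: int, i: int, j: int, L: np.ndarray, p_len: int, scheme: ScoringScheme
) -> float:
    """Score of the window t[L[i], L[j]] from its integer shared count.

    The window length is L[j] - L[i] + 1 text-sketch positions, counting
    the interleaved non-pattern k-mers, which contribute to |s| but not
    to the shared count.
    """
    s_len = int(L[j]) - int(L[i]) + 1
    return scheme.score_from_count(count, s_len, p_len)


@dataclass
class _MaximalityState:
    """Streamed maximality bookkeeping across the column scans.

    ``best_by_start[i]`` is the best score over all traversed cells with
    start row i; its running prefix maximum within a column equals the
    best score over all windows containing the current cell. ``pending``
    keeps, per start row, the latest final mapping found (the per-start
    compaction slot of the output list: a new final mapping at an
    already-seen start emits the stored one and takes its slot).
    """

    best_by_start: np.ndarray
    pending: dict[int, FinalMapping] = field(default_factory=dict)
    emitted: list = field(default_factory=list)

    def flush(self) -> list:
        self.emitted.extend(self.pending.values())
        self.pending.clear()
        return self.emitted


def _scan_column(
    col: DPColumn,
    L: np.ndarray,
    p_len: int,
    scheme: ScoringScheme,
    thr: float,
    state: _MaximalityState,
) -> None:
    """Emit the final mappings of one column (rows ascending)."""
    j = col.j
    vals = col.values
    n = j + 1
    s_len = (int(L[j]) - L[:n] + 1).astype(np.float64)
    if scheme.kind == "linear":
        scores = (1 + 2 * scheme.w) * vals - scheme.w * (s_len + p_len)
    else:
        scores = vals / (s_len + p_len - vals)
    left_ok = np.empty(n, dtype=bool)
    left_ok[:-1] = vals[:-1] == vals[1:] + 1
    left_ok[-1] = True  # diagonal, always reasonable
    reasonable = left_ok
    if col.i_star > 0:
        reasonable = reasonable.copy()
        reasonable[: col.i_star] = False

    prev_best = state.best_by_start[:n]
    pm = np.maximum.accumulate(np.maximum(prev_best, scores))
    running = np.empty(n)
    running[0] = prev_best[0]
    np.maximum(pm[:-1], prev_best[1:], out=running[1:])
    emit = reasonable & (scores >= thr - SCORE_EPS) & ~(running > scores)
    for i in np.flatnonzero(emit):
        i = int(i)
        fm = FinalMapping(
            i=i, j=j, a=int(L[i]), b=int(L[j]),
            count=int(vals[i]), score=float(scores[i]), threshold=thr,
        )
        if i in state.pending:
            state.emitted.append(state.pending[i])
        state.pending[i] = fm
    np.maximum(prev_best, scores, out=prev_best)


def collect_final_mappings(
    columns,
    L: np.ndarray,
    p_len: int,
    scheme: ScoringScheme,
    thr: float,
) -> list[FinalMapping]:
    """Run the maximality/reasonability scan over streamed columns.

    ``columns`` yields DPColumn objects in traversal order (last column
    first, each with its i_star resolved); rows are scanned ascending.
    """
    state = _MaximalityState(best_by_start=np.full(len(L), -np.inf))
    for col in columns:
        _scan_column(col, L, p_len, scheme, thr, state)
    out = state.flush()
    out.sort(key=lambda m: (m.a, m.b))
    return out


def find_mappings(
    t: Sketch,
    p: Sketch,
    scheme: ScoringScheme | None = None,
    thr: float | None = None,
    engine: str = "fast",
) -> list[FinalMapping]:
    """All final mappings of pattern sketch p in text sketch t.

    ``thr`` overrides the scheme's threshold rule (useful when the
    threshold comes from a per-read-length calibration model). Results
    are sorted by (a, b); base coordinates are attached when t carries
    offsets. ``engine`` selects the vectorized or the scalar reference
    column stream (identical output).
    """
    if scheme is None:
        scheme = ScoringScheme()
    if len(p) == 0:
        raise ValueError("pattern sketch must be non-empty")
    p_counts = count_occurrences(p)
    p_len = len(p)
    if thr is None:
        thr = scheme.threshold(p_len)
    if len(t) == 0:
        return []
    shared = build_shared_positions(t, p_counts)
    L = shared.L
    if shared.ell == 0:
        return []
    stream = {"fast": _columns_fast, "reference": _columns_reference}[engine]
    out = collect_final_mappings(stream(t.kmers, L, p_counts), L, p_len, scheme, thr)
    if len(t.offsets):
        for m in out:
            m.ref_id = t.record_id
            m.start = int(t.offsets[m.a])
            m.end = int(t.offsets[m.b]) + t.k
    return out
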