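"""k-mer enumeration, sketches, and occurrence profiles.

A *sketch* of a string T is an ordered subsequence of T's k-mer sequence,
with each retained k-mer carrying its 0-based start offset in T. Two
sketch constructions are provided: the classic (w, k)-minimizer sketch
(the minimum k-mer of every window of w consecutive k-mers under a seeded
hash or lexicographic order) and FracMinHash (keep every k-mer whose
uniform hash value is at most a sampling rate q). Downstream scoring and
mapping treat sketches purely as ordered multisets of tokens, so the
`kmers` field may hold arbitrary hashable tokens in tests.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Sequence

import numpy as np

from ._hash import canonical_kmer, encode_bases, hash_token, pack_kmers, splitmix64

__all__ = [
    "KmerizedString",
    "Sketch",
    "OccurrenceProfile",
    "enumerate_kmers",
    "minimizer_sketch",
    "fracminhash_sketch",
    "count_occurrences",
    "filter_high_frequency",
]


@dataclass
class KmerizedString:
    """All overlapping k-mers of a source string, in order, with offsets.

    Runs of non-ACGT characters break the k-mer sequence: any window
    spanning such a character is skipped, so offsets need not be contiguous.
    """

    kmers: list[str]
    offsets: np.ndarray
    k: int
    #: 2-bit packed representation of each k-mer (uint64), present when
    #: every k-mer is pure ACGT and k <= 32; used for fast hashing.
    packed: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass
class Sketch:
    """An ordered subsequence of a k-mer sequence.

    ``method`` is one of ``identity`` (the full k-mer sequence),
    ``minimizer`` or ``fracminhash``; ``params`` records the method's
    parameters (``w_min`` window size, or ``q`` sampling rate).
    """

    kmers: list
    offsets: np.ndarray
    k: int
    method: str = "identity"
    params: dict = field(default_factory=dict)
    seed: int = 0
    record_id: str | None = None

    def __len__(self) -> int:
        return len(self.kmers)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        if len(self.kmers) != len(self.offsets):
            raise ValueError("kmers and offsets must have equal length")
        if len(self.offsets) > 1 and not (np.diff(self.offsets) > 0).all():
            raise ValueError("offsets must be strictly increasing")

    @classmethod
    def from_tokens(cls, tokens: Sequence[Hashable], k: int = 1, **kw) -> "Sketch":
        """Build a sketch over arbitrary tokens (unit spacing offsets)."""
        return cls(list(tokens), np.arange(len(tokens)), k=k, **kw)


@dataclass
class OccurrenceProfile:
    """Multiset view of a sketch: k-mer -> occurrence count.

    ``total`` always equals the length of the summarized sequence, so it
    doubles as |s| / |p| in score formulas.
    """

    counts: dict
    total: int

    @classmethod
    def from_kmers(cls, kmers: Sequence[Hashable]) -> "OccurrenceProfile":
        c = Counter(kmers)
        return cls(dict(c), sum(c.values()))

    def __getitem__(self, kmer) -> int:
        return self.counts.get(kmer, 0)

    def __contains__(self, kmer) -> bool:
        return kmer in self.counts


def enumerate_kmers(seq: str, k: int, circular: bool = False) -> KmerizedString:
    """All overlapping k-mers of ``seq`` with their 0-based offsets.

    With ``circular=True`` the last k-1 windows wrap around to the start
    (offsets then run 0..len(seq)-1), which matches scoring against a
    circular-string mutation model; wrap k-mers containing non-ACGT
    characters are skipped like any other.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    src = seq.upper()
    if circular and len(src) >= k:
        n = len(src)
        src = src + src[: k - 1]
    codes = encode_bases(src)
    valid = codes != 255
    kmers: list[str] = []
    offsets: list[int] = []
    packed_parts: list[np.ndarray] = []
    # split into maximal ACGT runs; enumerate windows inside each run
    if valid.any():
        boundaries = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
        for start, stop in zip(boundaries[::2], boundaries[1::2]):
            if stop - start < k:
                continue
            for off in range(start, stop - k + 1):
                kmers.append(src[off : off + k])
                offsets.append(off)
            if k <= 32:
                packed_parts.append(pack_kmers(codes[start:stop], k))
    packed = None
    if k <= 32 and len(kmers) and sum(len(p) for p in packed_parts) == len(kmers):
        packed = np.concatenate(packed_parts)
    return KmerizedString(kmers, np.asarray(offsets, dtype=np.int64), k, packed)


def _order_keys(ks: KmerizedString, order: str, seed: int, kmers: list[str]) -> list:
    """Comparable sort keys per k-mer position for minimizer selection."""
    if order == "lex":
        return kmers
    if order != "hash":
        raise ValueError(f"unknown minimizer order {order!r}")
    if ks.packed is not None and kmers is ks.kmers:
        return splitmix64(ks.packed, seed).tolist()
    return [hash_token(x, seed) for x in kmers]


def minimizer_sketch(
    ks: KmerizedString,
    w_min: int,
    order: str = "hash",
    seed: int = 0,
    canonical: bool = False,
) -> Sketch:
    """(w, k)-minimizer sketch: the minimum k-mer of every window of
    ``w_min`` consecutive k-mers, ties broken by leftmost position.

    Consecutive windows selecting the same position contribute a single
    entry. Sequences with fewer than ``w_min`` k-mers yield an empty
    sketch (they contain no complete window).
    """
    if w_min < 1:
        raise ValueError(f"w_min must be >= 1, got {w_min}")
    kmers = [canonical_kmer(x) for x in ks.kmers] if canonical else ks.kmers
    keys = _order_keys(ks, order, seed, kmers)
    n = len(kmers)
    picked: list[int] = []
    window: deque[int] = deque()  # indices; keys non-decreasing front to back
    for j in range(n):
        while window and keys[window[-1]] > keys[j]:
            window.pop()
        window.append(j)
        if window[0] <= j - w_min:
            window.popleft()
        if j >= w_min - 1:
            if not picked or picked[-1] != window[0]:
                picked.append(window[0])
    return Sketch(
        [kmers[i] for i in picked],
        ks.offsets[picked] if picked else np.empty(0, dtype=np.int64),
        ks.k,
        method="minimizer",
        params={"w_min": w_min, "order": order, "canonical": canonical},
        seed=seed,
    )


def fracminhash_sketch(
    ks: KmerizedString,
    q: float,
    seed: int = 0,
    canonical: bool = False,
    hash_fn: Callable[[str], float] | None = None,
) -> Sketch:
    """FracMinHash sketch: every k-mer x with h(x) <= q, in source order.

    ``h`` maps a k-mer uniformly to [0, 1]; all occurrences of a retained
    k-mer are retained. ``hash_fn`` may inject a custom h (used in tests
    to pin which k-mers pass).
    """
    if not 0 < q <= 1:
        raise ValueError(f"sampling rate q must be in (0, 1], got {q}")
    kmers = [canonical_kmer(x) for x in ks.kmers] if canonical else ks.kmers
    if hash_fn is not None:
        mask = np.array([hash_fn(x) <= q for x in kmers], dtype=bool)
    elif ks.packed is not None and not canonical:
        cutoff = np.uint64(min(int(q * 2.0**64), 2**64 - 1))
        mask = splitmix64(ks.packed, seed) <= cutoff
    else:
        unit = {x: hash_token(x, seed) / 2.0**64 for x in set(kmers)}
        mask = np.array([unit[x] <= q for x in kmers], dtype=bool)
    idx = np.flatnonzero(mask) if len(kmers) else np.empty(0, dtype=np.int64)
    return Sketch(
        [kmers[i] for i in idx],
        ks.offsets[idx] if len(idx) else np.empty(0, dtype=np.int64),
        ks.k,
        method="fracminhash",
        params={"q": q, "canonical": canonical},
        seed=seed,
    )


def count_occurrences(s: Sketch | KmerizedString | Sequence) -> OccurrenceProfile:
    """Occurrence profile (k-mer -> multiplicity) of a sketch or sequence."""
    kmers = s.kmers if hasattr(s, "kmers") else s
    return OccurrenceProfile.from_kmers(kmers)


def filter_high_frequency(
    s: Sketch, counts: OccurrenceProfile, max_occ: int
) -> Sketch:
    """Drop every occurrence of any k-mer occurring more than ``max_occ``
    times according to ``counts`` (typically the profile of ``s`` itself,
    i.e. the reference sketch); order is preserved.

    Repetitive references make the shared-position list quadratically
    expensive, so over-frequent minimizers are excluded up front.
    """
    if max_occ < 1:
        raise ValueError(f"max_occ must be >= 1, got {max_occ}")
    keep = [i for i, x in enumerate(s.kmers) if counts[x] <= max_occ]
    return replace(
        s,
        kmers=[s.kmers[i] for i in keep],
        offsets=s.offsets[keep] if keep else np.empty(0, dtype=np.int64),
    )
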