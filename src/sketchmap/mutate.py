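"""Generative mutation model for read simulation and threshold calibration.

Each source position i independently draws an action a_i in
{sub, del, unchanged} (probabilities p_sub, p_del, 1 - p_sub - p_del) and
an insertion length b_i from a geometric distribution on {0, 1, 2, ...}
with mean p_ins, i.e. P(b_i = 0) = 1 / (1 + p_ins). The mutated string is
built by first substituting (uniformly among the three other bases), then
inserting b_i uniform-random bases before each surviving position, then
deleting the positions marked del. A per-k-mer occurrence therefore
survives unmutated with probability

    alpha = (1 - p_del - p_sub)^k / (p_ins + 1)^(k-1)

(all k actions unchanged, all k-1 internal insertion slots empty), the
quantity driving the closed-form expected score.

The model is defined on circular strings, where every position has an
insertion slot before it; on linear strings the construction is the same
(insertions before position 0 land at the front, and there is no extra
slot after the last position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MutationParams",
    "MutationTrace",
    "mutate",
    "random_dna",
    "distinct_kmer_string",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = {c: i for i, c in enumerate("ACGT")}

#: action codes in MutationTrace.actions
UNCHANGED, SUB, DEL = 0, 1, 2


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class MutationParams:
    """Per-position substitution/deletion probabilities and mean insertion
    length (all unitless rates)."""

    p_sub: float = 0.0
    p_del: float = 0.0
    p_ins: float = 0.0

    def __post_init__(self) -> None:
        if self.p_sub < 0 or self.p_del < 0 or self.p_ins < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.p_sub + self.p_del > 1:
            raise ValueError(
                f"p_sub + p_del must be <= 1, got {self.p_sub + self.p_del}"
            )

    @classmethod
    def from_total_rate(
        cls, rate: float, ratio: tuple[float, float, float] = (6, 50, 54)
    ) -> "MutationParams":
        """Split a total mutation rate in a sub:ins:del ratio."""
        total = sum(ratio)
        return cls(
            p_sub=rate * ratio[0] / total,
            p_ins=rate * ratio[1] / total,
            p_del=rate * ratio[2] / total,
        )


@dataclass
class MutationTrace:
    """What happened at each source position.

    ``track[i]`` is the position of source character i in the mutated
    string, or -1 if it was deleted.
    """

    actions: np.ndarray
    insertion_lengths: np.ndarray
    track: np.ndarray
    n: int


def mutate(
    S: str,
    params: MutationParams,
    seed: int | np.random.Generator = 0,
    circular: bool = False,
) -> tuple[str, MutationTrace]:
    """Apply the mutation model to ``S``; returns (S', trace).

    ``circular`` is bookkeeping only: insertions drawn for position 0 sit
    between the last and first characters of a circular string, which
    when linearized is the front of the output either way.
    """
    if not S:
        raise ValueError("cannot mutate an empty string")
    rng = _rng(seed)
    n = len(S)
    codes = np.array([_BASE_TO_CODE[c] for c in S.upper()], dtype=np.uint8)

    u = rng.random(n)
    actions = np.full(n, UNCHANGED, dtype=np.int8)
    actions[u < params.p_sub] = SUB
    actions[(u >= params.p_sub) & (u < params.p_sub + params.p_del)] = DEL

    if params.p_ins > 0:
        # geometric on {0,1,...} with success prob 1/(1+p_ins), mean p_ins
        b = rng.geometric(1.0 / (1.0 + params.p_ins), n).astype(np.int64) - 1
    else:
        b = np.zeros(n, dtype=np.int64)

    sub_mask = actions == SUB
    new_codes = codes.copy()
    if sub_mask.any():
        # uniform among the three other bases
        shift = rng.integers(1, 4, int(sub_mask.sum()), dtype=np.uint8)
        new_codes[sub_mask] = (codes[sub_mask] + shift) % 4

    keep = actions != DEL
    seg_len = b + keep.astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(seg_len)[:-1]))
    total = int(seg_len.sum())
    out = np.empty(total, dtype=np.uint8)

    char_pos = starts + b  # slot of source char i, only meaningful if kept
    out[char_pos[keep]] = new_codes[keep]
    ins_mask = np.ones(total, dtype=bool)
    ins_mask[char_pos[keep]] = False
    n_ins = int(ins_mask.sum())
    if n_ins:
        out[ins_mask] = rng.integers(0, 4, n_ins, dtype=np.uint8)

    track = np.where(keep, char_pos, -1)
    mutated = _BASES[out].tobytes().decode("ascii")
    return mutated, MutationTrace(actions, b, track, n)


def random_dna(n: int, seed: int | np.random.Generator = 0) -> str:
    """i.i.d. uniform string over {A, C, G, T} of length n."""
    if n < 0:
        raise ValueError("length must be >= 0")
    if n == 0:
        return ""
    rng = _rng(seed)
    return _BASES[rng.integers(0, 4, n, dtype=np.uint8)].tobytes().decode("ascii")


def distinct_kmer_string(
    n: int,
    k: int,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1_000_000,
    circular: bool = False,
) -> str:
    """Random DNA string of length n whose k-mers are pairwise distinct.

    Built left to right with backtracking: each next base is tried in
    random order, rejecting any base whose new k-mer was seen before.
    With ``circular=True`` the wrap-around k-mers are required to be
    distinct as well, so all n circular k-mers differ. Such strings
    approximately satisfy the mutation-distinctness assumption (mutations
    essentially never recreate a k-mer of the original), making the
    closed-form expected score applicable.
    """
    n_kmers = n if circular else n - k + 1
    if n_kmers > 4**k:
        raise ValueError(
            f"cannot place {n_kmers} distinct {k}-mers in an alphabet of 4^{k}"
        )
    rng = _rng(seed)
    tries = 0
    codes: list[int] = []
    seen: list[int] = []  # packed k-mer at each position >= k-1
    seen_set: set[int] = set()
    options: list[list[int]] = []
    mask = (1 << (2 * k)) - 1

    def packed_at(pos_codes: list[int]) -> int:
        v = 0
        for c in pos_codes[-k:]:
            v = (v << 2) | c
        return v

    while len(codes) < n:
        if len(options) == len(codes):
            options.append(list(rng.permutation(4)))
        advanced = False
        while options[-1]:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"distinct_kmer_string exceeded max_tries={max_tries}"
                )
            c = int(options[-1].pop())
            codes.append(c)
            if len(codes) < k:
                advanced = True
                break
            v = packed_at(codes)
            if v in seen_set:
                codes.pop()
                continue
            seen.append(v)
            seen_set.add(v)
            advanced = True
            break
        if not advanced:
            # dead end: undo last placed character
            options.pop()
            if not codes:
                raise RuntimeError("distinct_kmer_string could not place any base")
            codes.pop()
            if len(codes) >= k - 1 and seen:
                seen_set.discard(seen.pop())

    s = _BASES[np.array(codes, dtype=np.uint8)].tobytes().decode("ascii")
    if circular:
        # verify the k-1 wrap k-mers too; retry with fresh randomness if not
        wrap = s + s[: k - 1]
        kmers = {wrap[i : i + k] for i in range(n)}
        if len(kmers) < n:
            return distinct_kmer_string(n, k, rng, max_tries - tries, circular=True)
    return s
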