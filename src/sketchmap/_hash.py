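"""Seeded 64-bit hashing of k-mers.

DNA k-mers (k <= 32) are packed into a 64-bit integer with 2 bits per base
and mixed with a splitmix64 finalizer; this is vectorizable with numpy and
deterministic across processes. Arbitrary (non-ACGT) tokens fall back to a
keyed blake2b digest so that generic token sketches hash consistently too.
"""

from __future__ import annotations

import hashlib

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i
    _CODE[_c + 32] = _i  # lowercase

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_U64 = np.uint64


def encode_bases(seq: str) -> np.ndarray:
    """2-bit codes of ``seq``; 255 marks characters outside {A,C,G,T}."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every window of k consecutive 2-bit codes into a uint64.

    Caller guarantees all codes are valid (< 4) and k <= 32.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=_U64)
    out = np.zeros(n, dtype=_U64)
    c = codes.astype(_U64)
    for j in range(k):
        out = (out << _U64(2)) | c[j : j + n]
    return out


def splitmix64(x: np.ndarray | int, seed: int = 0) -> np.ndarray | int:
    """splitmix64 finalizer of x XOR a seed-derived key (vectorized)."""
    with np.errstate(over="ignore"):
        z = np.asarray(x, dtype=_U64) ^ _U64((seed * 0x9E3779B97F4A7C15 + 0x243F6A8885A308D3) & 0xFFFFFFFFFFFFFFFF)
        z = (z + _U64(0x9E3779B97F4A7C15)) & _U64(0xFFFFFFFFFFFFFFFF)
        z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(0xFFFFFFFFFFFFFFFF)
        z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(0xFFFFFFFFFFFFFFFF)
        z = z ^ (z >> _U64(31))
    if np.isscalar(x) or np.ndim(x) == 0:
        return int(z)
    return z


def hash_token(token: str, seed: int = 0) -> int:
    """Seeded 64-bit hash of one token (DNA fast path, blake2b otherwise)."""
    codes = encode_bases(token)
    if len(token) <= 32 and codes.size and not (codes == 255).any():
        packed = 0
        for c in codes:
            packed = (packed << 2) | int(c)
        return int(splitmix64(packed, seed))
    digest = hashlib.blake2b(
        token.encode(), digest_size=8, key=seed.to_bytes(8, "little", signed=False)
    ).digest()
    return int.from_bytes(digest, "little")


def hash_unit_interval(token: str, seed: int = 0) -> float:
    """Map a token to [0, 1] for FracMinHash membership tests."""
    return hash_token(token, seed) / 2.0**64


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))


def canonical_kmer(kmer: str) -> str:
    """Strand-min representative: the lexicographic min of kmer and its RC."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc
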