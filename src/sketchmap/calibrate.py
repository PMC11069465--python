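"""Score-threshold calibration, analytical and simulation-based.

Analytical route (FracMinHash only): under the mutation model with the
mutation-distinctness assumption, the expected linear score of the
sketches of a circular string and its mutated copy is

    E[sc_l(s, s'; w)] = n_kmers * q * (alpha + w * (2*alpha - 2 + p_del - p_ins))

with alpha = (1 - p_del - p_sub)^k / (p_ins + 1)^(k-1). ``n_kmers`` is
the k-mer count of the un-sketched string (n for a circular string of
length n); multiplying by the sampling rate q gives the expected sketch
size.

Simulation route (any sketch): draw random strings S of a given length,
mutate each to S', sketch both, score the pair; the empirical lower
quantile of the scores is the threshold that would retain the desired
fraction of true mappings. Repeating at several lengths gives a
piecewise-linear threshold model interpolated over read length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil

import numpy as np

from .mutate import MutationParams, distinct_kmer_string, mutate, random_dna, _rng
from .score import ScoringScheme
from .sketch import (
    Sketch,
    count_occurrences,
    enumerate_kmers,
    fracminhash_sketch,
    minimizer_sketch,
)

__all__ = [
    "alpha",
    "expected_linear_score",
    "SketcherConfig",
    "ScoreSample",
    "simulate_score_distribution",
    "threshold_from_quantile",
    "ThresholdModel",
    "calibrate_thresholds",
]


def alpha(params: MutationParams, k: int) -> float:
    """Survival probability of one k-mer occurrence under the model."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return (1 - params.p_del - params.p_sub) ** k / (params.p_ins + 1) ** (k - 1)


def expected_linear_score(
    n_kmers: int, q: float, k: int, params: MutationParams, w: float
) -> float:
    """Closed-form expectation of sc_l(s, s'; w) under FracMinHash rate q."""
    if not w > 0:
        raise ValueError(f"w must be > 0, got {w}")
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    a = alpha(params, k)
    return n_kmers * q * (a + w * (2 * a - 2 + params.p_del - params.p_ins))


@dataclass(frozen=True)
class SketcherConfig:
    """Which sketch to build during calibration/mapping simulations."""

    method: str = "fracminhash"  # fracminhash | minimizer | identity
    k: int = 15
    q: float = 0.2
    w_min: int = 10
    seed: int = 0
    circular: bool = False

    def sketch(self, seq: str) -> Sketch:
        ks = enumerate_kmers(seq, self.k, circular=self.circular)
        if self.method == "identity":
            return Sketch(ks.kmers, ks.offsets, self.k)
        if self.method == "minimizer":
            return minimizer_sketch(ks, self.w_min, seed=self.seed)
        if self.method == "fracminhash":
            return fracminhash_sketch(ks, self.q, seed=self.seed)
        raise ValueError(f"unknown sketch method {self.method!r}")


@dataclass
class ScoreSample:
    """Simulated score distribution plus resampling diagnostics."""

    scores: np.ndarray
    length: int
    mean_pattern_len: float
    resampled: int = 0


def simulate_score_distribution(
    length: int,
    params: MutationParams,
    sketcher: SketcherConfig,
    scheme: ScoringScheme,
    reps: int,
    seed: int | np.random.Generator = 0,
    distinct_kmers: bool = False,
) -> ScoreSample:
    """Scores of sketch(S) vs sketch(S') for ``reps`` independent pairs.

    S is uniformly random DNA of ``length`` bp (or a distinct-k-mer
    string when ``distinct_kmers``, for checking the analytical formula);
    pairs where both sketches come out empty carry no score and are
    redrawn, counted in ``resampled``.

    A fresh hash seed is drawn per replicate (from the same rng, so runs
    stay deterministic): the score model's expectation averages over the
    hash function, and with a single fixed hash the realized sampling
    rate of the finite k-mer universe differs from q by enough to show
    up at large replicate counts.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = _rng(seed)
    scores = np.empty(reps)
    p_lens = np.empty(reps)
    resampled = 0
    i = 0
    while i < reps:
        if distinct_kmers:
            S = distinct_kmer_string(
                length, sketcher.k, rng, circular=sketcher.circular
            )
        else:
            S = random_dna(length, rng)
        S2, _ = mutate(S, params, rng, circular=sketcher.circular)
        sk = replace(sketcher, seed=int(rng.integers(2**62)))
        s = sk.sketch(S)
        s2 = sk.sketch(S2) if S2 else Sketch([], [], sketcher.k)
        if len(s) == 0 and len(s2) == 0:
            resampled += 1
            if resampled > 100 * reps:
                raise RuntimeError("too many degenerate (empty, empty) sketch pairs")
            continue
        scores[i] = scheme.score(count_occurrences(s), count_occurrences(s2))
        p_lens[i] = len(s)
        i += 1
    return ScoreSample(scores, length, float(p_lens.mean()), resampled)


def threshold_from_quantile(scores, confidence: float) -> float:
    """Largest cutoff keeping at least ``confidence`` of the scores.

    Lower empirical quantile: the order statistic at (1-based) index
    ceil((1 - confidence) * len(scores)), clamped to the minimum score,
    so that >= confidence of the simulated mappings meet the cutoff.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    scores = np.sort(np.asarray(scores, dtype=float))
    if scores.size == 0:
        raise ValueError("cannot take a quantile of an empty score sample")
    idx = max(1, ceil((1 - confidence) * scores.size))
    return float(scores[idx - 1])


@dataclass
class ThresholdModel:
    """thr as a function of read length: a constant, or piecewise-linear
    interpolation between (length, threshold) knots, clamped outside the
    knot range.

    Thresholds are keyed by read length in bp rather than sketch length -
    that is what a mapper knows per read before sketching - and
    ``mean_pattern_len`` records the mean pattern-sketch size observed
    per knot for transparency.
    """

    mode: str = "constant"  # constant | table
    value: float = 0.0
    lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_pattern_len: np.ndarray = field(default_factory=lambda: np.empty(0))
    confidence: float | None = None
    scheme_kind: str = "linear"

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.mode not in ("constant", "table"):
            raise ValueError(f"unknown threshold model mode {self.mode!r}")
        if self.mode == "table":
            if self.lengths.size == 0:
                raise ValueError("table threshold model needs at least one knot")
            if self.lengths.size != self.thresholds.size:
                raise ValueError("knot lengths and thresholds differ in size")
            if self.lengths.size > 1 and not (np.diff(self.lengths) > 0).all():
                raise ValueError("knot lengths must be strictly increasing")

    def evaluate(self, read_length: float) -> float:
        if self.mode == "constant":
            return float(self.value)
        return float(np.interp(read_length, self.lengths, self.thresholds))

    __call__ = evaluate


def calibrate_thresholds(
    lengths,
    params: MutationParams,
    sketcher: SketcherConfig,
    scheme: ScoringScheme,
    confidences,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[float, ThresholdModel]:
    """Simulate at each length, take per-confidence quantiles, and return
    one interpolating ThresholdModel per confidence level."""
    rng = _rng(seed)
    lengths = sorted(int(x) for x in lengths)
    samples = [
        simulate_score_distribution(n, params, sketcher, scheme, reps, rng)
        for n in lengths
    ]
    models: dict[float, ThresholdModel] = {}
    for conf in confidences:
        thr = [threshold_from_quantile(s.scores, conf) for s in samples]
        models[conf] = ThresholdModel(
            mode="table",
            lengths=np.asarray(lengths, dtype=float),
            thresholds=np.asarray(thr, dtype=float),
            mean_pattern_len=np.asarray([s.mean_pattern_len for s in samples]),
            confidence=conf,
            scheme_kind=scheme.kind,
        )
    return models
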