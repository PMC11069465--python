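"""Long-read simulation from a reference.

Read lengths follow a gamma distribution (defaults emulating a PacBio
HiFi-like run: mean 9000 bp, sd 7000 bp), start positions are uniform,
strands are drawn uniformly, and sequencing errors come from the
mutation model with a total rate split sub:ins:del = 6:50:54 by default.
Each FASTA header encodes the true origin (record, 0-based half-open
interval, strand) for downstream evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._hash import reverse_complement
from .mutate import MutationParams, _rng, mutate

__all__ = ["ReadSimConfig", "simulate_reads"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadSimConfig:
    n_reads: int = 100
    mean_length: float = 9000.0
    sd_length: float = 7000.0
    rate: float = 0.002
    ratio: tuple[float, float, float] = (6, 50, 54)  # sub : ins : del
    min_length: int = 100
    strands: str = "both"  # both | forward

    @property
    def mutation_params(self) -> MutationParams:
        return MutationParams.from_total_rate(self.rate, self.ratio)


def simulate_reads(
    references: list[tuple[str, str]],
    config: ReadSimConfig = ReadSimConfig(),
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """(header, sequence) pairs; headers look like
    ``read42 origin=chr1:1000-9500:+ length=8500``.

    Records are chosen with probability proportional to length. A drawn
    length exceeding the record is capped to the record length (with a
    warning), matching the behaviour of resampling with a cap.
    """
    rng = _rng(seed)
    if not references:
        raise ValueError("need at least one reference record")
    lens = np.array([len(s) for _, s in references], dtype=float)
    if (lens < config.min_length).all():
        raise ValueError("all reference records shorter than min read length")
    weights = lens / lens.sum()
    shape = (config.mean_length / config.sd_length) ** 2
    scale = config.sd_length**2 / config.mean_length
    params = config.mutation_params

    out: list[tuple[str, str]] = []
    capped = 0
    for idx in range(config.n_reads):
        rec = int(rng.choice(len(references), p=weights))
        name, seq = references[rec]
        r = int(round(rng.gamma(shape, scale)))
        r = max(config.min_length, r)
        if r > len(seq):
            r = len(seq)
            capped += 1
        start = int(rng.integers(0, len(seq) - r + 1))
        frag = seq[start : start + r]
        strand = "+" if config.strands == "forward" or rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        read, _ = mutate(frag, params, rng) if frag else (frag, None)
        header = (
            f"read{idx} origin={name}:{start}-{start + r}:{strand} "
            f"length={len(read)}"
        )
        out.append((header, read))
    if capped:
        logger.warning("%d read lengths were capped to the record length", capped)
    return out
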