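import numpy as np
import pytest

from sketchmap import OccurrenceProfile, Sketch


@pytest.fixture
def toy_instance():
    """The worked 4-token text / 2-token pattern instance used across the
    DP tests: t = (a, x, b, a), p = (a, b)."""
    return Sketch.from_tokens(list("axba")), Sketch.from_tokens(list("ab"))


@pytest.fixture
def make_random_instance():
    """Factory for random token instances over a small alphabet."""

    def _make(rng, max_t=60, max_p=15, alphabet=4):
        T = rng.integers(0, alphabet, rng.integers(1, max_t + 1))
        P = rng.integers(0, alphabet, rng.integers(1, max_p + 1))
        return Sketch.from_tokens(T.tolist()), Sketch.from_tokens(P.tolist())

    return _make


@pytest.fixture
def make_random_profiles():
    """Factory for random occurrence-profile pairs over 4 tokens."""

    def _make(rng, max_len=20):
        a = rng.integers(0, 4, rng.integers(1, max_len + 1)).tolist()
        b = rng.integers(0, 4, rng.integers(1, max_len + 1)).tolist()
        return OccurrenceProfile.from_kmers(a), OccurrenceProfile.from_kmers(b)

    return _make
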