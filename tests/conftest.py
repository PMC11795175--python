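from __future__ import annotations

import numpy as np
import pytest

from sigoverlap.signatures import GeneEntry, Signature, Universe


def make_signature(name, scores, species="mouse"):
    """Signature from a mapping symbol -> signed score."""
    return Signature(
        name, species, tuple(GeneEntry(s, v) for s, v in scores.items())
    )


def random_signature(rng, name, symbols, size):
    """Random signature over the given symbol pool with continuous scores."""
    chosen = rng.choice(np.asarray(list(symbols)), size=size, replace=False)
    scores = rng.standard_normal(size)
    scores[scores == 0.0] = 0.5
    return make_signature(name, dict(zip(chosen, scores)))


@pytest.fixture
def small_universe():
    return Universe(frozenset(f"G{i:03d}" for i in range(1, 41)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
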