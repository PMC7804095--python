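"""Shared fixtures: seeded noisy-window generators used across modules."""

from __future__ import annotations

import numpy as np
import pytest

from wincorr.params import Params
from wincorr.synthetic import DEFAULT_ERROR_MIX, _mutate, random_genome


@pytest.fixture
def params() -> Params:
    return Params()


def mutate(seq: str, error_rate: float, rng) -> str:
    """Noisy copy of seq with the default indel-dominant error mix."""
    return _mutate(seq, error_rate, DEFAULT_ERROR_MIX, rng)[0]


def make_noisy_window(
    seed: int,
    length: int = 500,
    coverage: int = 12,
    error_rate: float = 0.12,
):
    """(truth, seqs): a random window truth plus noisy copies of it; the
    first copy plays the window template."""
    rng = np.random.default_rng(seed)
    truth = random_genome(length, 0.5, seed + 10_000)
    seqs = [mutate(truth, error_rate, rng) for _ in range(coverage)]
    return truth, seqs


@pytest.fixture
def noisy_window():
    return make_noisy_window
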