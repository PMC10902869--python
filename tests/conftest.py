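"""Shared fixtures: session designs, a reduced-raster filter bank, and
simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from seqbias import (
    FilterBank,
    ObserverParams,
    StimulusParams,
    assign_correct_labels,
    build_session,
    generate_counterbalanced_sequence,
    lag1_params,
    simulate_session,
)

REDUCED = StimulusParams(pixels_per_degree=6.4)  # 64 x 64 raster


@pytest.fixture(scope="session")
def bank64() -> FilterBank:
    return FilterBank(REDUCED)


@pytest.fixture(scope="session")
def session_design():
    return build_session(seed=11)


@pytest.fixture(scope="session")
def big_neutral():
    """A 100k-trial counterbalanced environment with labels, for
    law-of-large-numbers checks on the observer."""
    seq = generate_counterbalanced_sequence(100_000, seed=5)
    return assign_correct_labels(seq, seed=6)


@pytest.fixture(scope="session")
def big_neutral_history_sim(big_neutral):
    """Responses of a lag-1 history observer (no lapses) on the 100k-trial
    neutral sequence; reused by closed-form and psychometric checks."""
    params = lag1_params(0.25, 0.25, slope=8.0, lapse_cw=0.0, lapse_ccw=0.0)
    return simulate_session(params, big_neutral, seed=7)


@pytest.fixture(scope="session")
def null_observer() -> ObserverParams:
    return ObserverParams(slope=0.0, lapse_cw=0.0, lapse_ccw=0.0)
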