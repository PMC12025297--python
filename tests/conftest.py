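"""Shared fixtures.

The simulation study (clean recording + trained reconstructor) and the four
spike-protocol sweeps are expensive, so they are computed once per session
and shared between the module tests and the acceptance tests.
"""

import warnings

import numpy as np
import pytest

from eitrpca.experiments import (
    run_channel_sweep,
    run_filter_comparison,
    run_magnitude_sweep,
    run_width_sweep,
    simulate_study,
)

SEED = 0


@pytest.fixture(scope="session")
def ctx():
    """Clean thorax study: phantom, 192x600 recording, reconstructor."""
    return simulate_study(seed=SEED)


@pytest.fixture(scope="session")
def magnitude_sweep(ctx):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_magnitude_sweep(seed=SEED, ctx=ctx)


@pytest.fixture(scope="session")
def width_sweep(ctx):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_width_sweep(seed=SEED, ctx=ctx)


@pytest.fixture(scope="session")
def channel_sweep(ctx):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_channel_sweep(seed=SEED, ctx=ctx)


@pytest.fixture(scope="session")
def filter_comparison():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_filter_comparison(seed=SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
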