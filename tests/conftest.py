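import numpy as np
import pytest

from facecue import (
    PAPER_MEDIAN_PARAMS,
    DesignSpec,
    ModelParams,
    build_design,
    simulate_responses,
)


@pytest.fixture(scope="session")
def median_params() -> ModelParams:
    """Group-median observer parameters used as the canonical test point."""
    return PAPER_MEDIAN_PARAMS


@pytest.fixture(scope="session")
def tiny_design():
    """Three-level grid, single repetition, old off: 11 trials."""
    return DesignSpec(
        morph_levels=(0.0, 0.5, 1.0), delta=0.15, n_reps=1, include_old=False
    )


@pytest.fixture(scope="session")
def default_trials():
    return build_design(DesignSpec(), seed=0)


@pytest.fixture(scope="session")
def opt_responses(default_trials, median_params):
    """One synthetic subject simulated from the optimal observer."""
    return simulate_responses("OPT", median_params, default_trials, seed=11, subject=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
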