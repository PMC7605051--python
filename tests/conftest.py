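import numpy as np
import pytest

from stereocoupling.inference import MCMCConfig, PriorSpec
from stereocoupling.stimulus import baseline_trial_schedule

PAPER_LEVELS = [0.0, 2.3, 4.6]


@pytest.fixture(scope="session")
def paper_schedule():
    """The baseline block of the study: 20 repeats x {0, 2.3, 4.6} x {convex, concave}."""
    return baseline_trial_schedule(20, PAPER_LEVELS, seed=1234)


@pytest.fixture(scope="session")
def default_priors():
    return PriorSpec()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short chains for tests that exercise contracts rather than accuracy."""
    return MCMCConfig(n_chains=2, n_samples=1500, n_burnin=800, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20210909)
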