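import numpy as np
import pytest

from arrowtime import make_chain_system, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def chain_system():
    """5-region causal chain: Gaussian-driven source, Laplace downstream."""
    return make_chain_system(5)


@pytest.fixture(scope="session")
def chain_cohort(chain_system):
    """10 subjects x 1000 points from the chain system (z-scored)."""
    return simulate_cohort(chain_system, n_subjects=10, n_time=1000, seed=7)


@pytest.fixture(scope="session")
def small_gaussian_cohort():
    """White-ish Gaussian cohort: 3 regions, 4 subjects x 200 points."""
    system = make_chain_system(3, family="gaussian", coupling=0.4, self_coupling=0.3)
    return simulate_cohort(system, n_subjects=4, n_time=200, seed=11)
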