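import numpy as np
import pytest

from trionurture import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-parameter cohort shared across read-only tests."""
    sim = SimConfig(n_families=800, n_snps=120, seed=7)
    return simulate_cohort(sim, seed=7)


@pytest.fixture(scope="session")
def large_cohort():
    """A bigger cohort for tests that need tighter Monte-Carlo error."""
    sim = SimConfig(n_families=10_000, n_snps=200, seed=11)
    return simulate_cohort(sim, seed=11)
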