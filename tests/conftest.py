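import numpy as np
import pytest

from opmdml import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """50-record default-spec cohort for I/O and encoding tests."""
    return generate_cohort(default_cohort_spec(n=50, seed=123))


@pytest.fixture(scope="session")
def cohort_681():
    """Study-sized default-spec cohort (one seed, shared across tests)."""
    return generate_cohort(default_cohort_spec(n=681, seed=0))


@pytest.fixture(scope="session")
def cohort_100k():
    """Large cohort for frequency / event-fraction checks."""
    return generate_cohort(default_cohort_spec(n=100_000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
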