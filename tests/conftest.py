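import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from vrss.synthetic import CohortConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The 28-participant study-structure cohort (no RR series, fast)."""
    return generate_cohort(CohortConfig(seed=1, generate_rr=False))


@pytest.fixture(scope="session")
def default_cohort_table(default_cohort):
    return default_cohort.cohort_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
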