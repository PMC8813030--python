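import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_partition():
    """12-component partition across the seven networks."""
    from dynconn.synthetic import default_partition

    return default_partition(12)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-subject default-parameter cohort, shared across tests."""
    from dynconn.synthetic import CohortSpec, simulate_cohort

    spec = CohortSpec(
        n_per_group={"HC": 2, "LTLE": 2, "RTLE": 2},
        n_components=12,
        n_timepoints=80,
        seed=42,
    )
    return spec, *simulate_cohort(spec)
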