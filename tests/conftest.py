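import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from querchol.synthetic import paper_scenarios, scenario

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundles():
    return paper_scenarios()


@pytest.fixture(scope="session")
def truths(bundles):
    return bundles[0]


@pytest.fixture(scope="session")
def fixtures(bundles):
    return bundles[1]


@pytest.fixture(scope="session")
def recovery_truth():
    return scenario("recovery")


@pytest.fixture(scope="session")
def published_truth():
    """Truth bundle carrying the published treatment constants (Q0 = 100)."""
    return scenario("with_quercetin_q100")


@pytest.fixture
def dense_grid():
    return np.linspace(0.0, 0.5, 26)
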