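import pytest
from hypothesis import settings, HealthCheck

from minicoag import (
    DEFAULT_PARAMETERS,
    OPTIMAL_PARAMETERS,
    SimulationProtocol,
    minimal_model,
    reference_model,
    simulate,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_625():
    """Reference-model trajectory over the 625 s calibration window."""
    return simulate(reference_model(), SimulationProtocol(t_end=625.0))


@pytest.fixture(scope="session")
def reference_5000():
    """Reference-model trajectory over the full 5000 s horizon."""
    return simulate(reference_model(), SimulationProtocol(t_end=5000.0))


@pytest.fixture(scope="session")
def minimal_default_5000():
    return simulate(minimal_model(DEFAULT_PARAMETERS), SimulationProtocol(t_end=5000.0))


@pytest.fixture(scope="session")
def minimal_optimal_5000():
    return simulate(minimal_model(OPTIMAL_PARAMETERS), SimulationProtocol(t_end=5000.0))


@pytest.fixture(scope="session")
def minimal_default_625():
    return simulate(minimal_model(DEFAULT_PARAMETERS), SimulationProtocol(t_end=625.0))
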