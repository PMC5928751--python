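import numpy as np
import pytest

from stgboundary.synthetic import (
    SimulationParams,
    make_event_schedule,
    make_gyrus,
    simulate_bold,
    simulate_ecog,
)


@pytest.fixture(scope="session")
def gyrus():
    return make_gyrus()


@pytest.fixture(scope="session")
def schedule():
    return make_event_schedule(seed=0)


@pytest.fixture(scope="session")
def one_run_schedule():
    return make_event_schedule(n_runs=1, seed=0)


@pytest.fixture(scope="session")
def noiseless_params():
    return SimulationParams().with_zero_noise()


@pytest.fixture(scope="session")
def noiseless_ecog(gyrus, noiseless_params):
    """Single anterior electrode, no noise: the generative identity fixture."""
    return simulate_ecog(
        gyrus, [20.0], 5, noiseless_params, seed=1, n_reference_channels=1
    )


@pytest.fixture(scope="session")
def noiseless_bold(gyrus, one_run_schedule, noiseless_params):
    return simulate_bold(gyrus, one_run_schedule, noiseless_params, seed=1)


@pytest.fixture(scope="session")
def default_bold(gyrus, schedule):
    return simulate_bold(gyrus, schedule, SimulationParams(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
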