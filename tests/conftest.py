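import numpy as np
import pytest

from nirseeg import fusion, paradigm
from nirseeg.simulate import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def noise_free_session():
    """Full 5-min noise-free session (the deterministic reference recording)."""
    return simulate_session(SimulationConfig(seed=0).noise_free(), n_samples=5)


@pytest.fixture(scope="session")
def noisy_session():
    return simulate_session(SimulationConfig(seed=0), n_samples=5)


@pytest.fixture(scope="session")
def trained_models(noisy_session):
    return fusion.train_models(noisy_session)


@pytest.fixture(scope="session")
def single_tap_schedule():
    """Initial 5-s rest followed by one 10-s left-hand tapping block."""
    return paradigm.EventSchedule(
        (
            paradigm.TaskBlock(paradigm.REST, 0.0, 5.0),
            paradigm.TaskBlock(paradigm.TAP_LEFT, 5.0, 10.0),
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
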