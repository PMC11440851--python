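import numpy as np
import pytest

from tacdelay.synthetic import (
    INPUT_PRESETS,
    SCHEDULES,
    SimulationSpec,
    input_function_tac,
    simulate_tissue,
)


@pytest.fixture(scope="session")
def h2o_schedule():
    return SCHEDULES("h2o")


@pytest.fixture(scope="session")
def idif_model():
    return INPUT_PRESETS["h2o_idif"]


@pytest.fixture(scope="session")
def idif_tac(h2o_schedule, idif_model):
    """Noise-free frame-averaged input-function TAC on the water schedule."""
    return input_function_tac(idif_model, h2o_schedule)


@pytest.fixture(scope="session")
def make_tissue(h2o_schedule, idif_model):
    """Factory for synthetic one-tissue TACs on the water schedule."""

    def _make(K1=60.0, k2=0.8, delay=0.0, sigma=0.0, seed=1):
        spec = SimulationSpec(
            K1=K1, k2=k2, delay=delay, sigma=sigma, seed=seed,
            schedule=h2o_schedule, input_model=idif_model,
        )
        return simulate_tissue(spec)

    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
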