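import numpy as np
import pytest

from bsconv.error_profile import BetaErrorModel


@pytest.fixture(scope="session")
def error_model() -> BetaErrorModel:
    """The chloroplast-derived error-rate distribution used throughout."""
    return BetaErrorModel(a=17.0, b=220.0)


@pytest.fixture(scope="session")
def default_simulation():
    """One full simulation grid run, shared by the tests that inspect it."""
    from bsconv.simulation import SimulationConfig, run_experiment

    config = SimulationConfig(seed=20240917)
    estimates, summary = run_experiment(config)
    return config, estimates, summary


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
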