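import numpy as np
import pytest

from lysedyn import FITTED_MEANS, NoiseModel, PopulationState


@pytest.fixture(scope="session")
def params():
    """Reference mean fitted parameter set."""
    return FITTED_MEANS


@pytest.fixture(scope="session")
def init_state():
    """Standard refresh: total density 0.01 a.u., stock mutant fraction 7e-5."""
    return PopulationState.from_total(0.01, 7e-5)


@pytest.fixture()
def no_noise():
    return NoiseModel(multiplicative_cv=0.0, additive_sd=0.0, baseline_offset=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
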