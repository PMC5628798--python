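import numpy as np
import pytest

from coolmass.model_core import ModelParameters, TemperatureSpec


@pytest.fixture(scope="session")
def params():
    """Default parameters: the discharge-regime gains used throughout."""
    return ModelParameters()


@pytest.fixture(scope="session")
def cooled_syn_int():
    """Combined-mechanism cooling to 15 degC with Q10,syn = 1.8."""
    return TemperatureSpec(T=15.0, T0=31.0, variant="SYN_INT",
                           q_syn=1.8, q_int=1.75)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
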