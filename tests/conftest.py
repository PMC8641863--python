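import numpy as np
import pytest

from fflnoise import ParameterSet, build_model, input_only_model, staircase
from fflnoise.input_signal import InputProtocol


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def protocol():
    return staircase()


@pytest.fixture(scope="session")
def constant_protocol():
    """Three plateaus at the reference level: 40 time units of equilibration
    before the final window used for statistics."""
    return InputProtocol(plateaus=(6.0, 6.0, 6.0), plateau_duration=20.0)


@pytest.fixture(scope="session")
def c1_or():
    return build_model("c1-OR")


@pytest.fixture(scope="session")
def input_model():
    return input_only_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211203)
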