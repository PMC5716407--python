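import numpy as np
import pytest

from protondose.curves import apply_response, calibrate_response, pristine_bragg
from protondose.materials import range_from_energy


@pytest.fixture(scope="session")
def dd190():
    return pristine_bragg(range_from_energy(190.0))


@pytest.fixture(scope="session")
def response_model(dd190):
    return calibrate_response(dd190)


@pytest.fixture(scope="session")
def do190(dd190, response_model):
    return apply_response(dd190, response_model)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
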