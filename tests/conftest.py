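import numpy as np
import pytest

from wfmp2rage import ProtocolParams, build_lut, make_binomial_pulse


@pytest.fixture(scope="session")
def params():
    return ProtocolParams()


@pytest.fixture(scope="session")
def water_pulse():
    return make_binomial_pulse(6, "water")


@pytest.fixture(scope="session")
def fat_pulse():
    return make_binomial_pulse(6, "fat")


@pytest.fixture(scope="session")
def nominal_lut(params):
    """Radial on-resonance look-up table, shared across tests (read-only)."""
    return build_lut(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
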