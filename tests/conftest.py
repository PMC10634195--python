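import numpy as np
import pytest

from evlipo.bands import default_axis, default_components


@pytest.fixture(scope="session")
def fingerprint_axis():
    """600-1800 cm^-1 fingerprint grid at 2 cm^-1 spacing."""
    return default_axis(600.0, 1800.0, 2.0)


@pytest.fixture(scope="session")
def fingerprint_components(fingerprint_axis):
    return default_components(fingerprint_axis)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
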