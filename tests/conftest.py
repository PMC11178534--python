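import numpy as np
import pytest
from hypothesis import settings

import retnpi as rn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model_256():
    """Default calibrated model eye at a fast test resolution."""
    return rn.default_eye_model((256, 256))


@pytest.fixture(scope="session")
def area_256(model_256):
    return rn.pixel_area_map(model_256)


@pytest.fixture(scope="session")
def model_512():
    return rn.default_eye_model((512, 512))


@pytest.fixture(scope="session")
def area_512(model_512):
    return rn.pixel_area_map(model_512)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
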