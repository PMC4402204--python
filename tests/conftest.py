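import numpy as np
import pytest
from hypothesis import settings

from spinedyn import ModelParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Standard parameter set."""
    return ModelParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
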