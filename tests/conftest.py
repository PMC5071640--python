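import numpy as np
import pytest

from icekit.types import SpectrumProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ty1_profile():
    return SpectrumProfile.ty1_rnapii()


@pytest.fixture(scope="session")
def uniform_profile():
    return SpectrumProfile.uniform(mut_per_kb=0.15)
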