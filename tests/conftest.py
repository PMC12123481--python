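import numpy as np
import pytest

from synchrospread.fields import SpatioTemporalField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_field(values, name=""):
    values = np.asarray(values, dtype=float)
    n, T = values.shape
    return SpatioTemporalField(values, np.arange(n), np.arange(T), name=name)


@pytest.fixture
def white_noise_field(rng):
    return make_field(rng.standard_normal((12, 31)))
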