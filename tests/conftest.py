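import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230828)


def random_centred_weights(rng, n, size=None):
    """Random weight vectors summing to zero (valid linear-test weights)."""
    shape = (n - 1,) if size is None else (size, n - 1)
    Om = rng.normal(size=shape)
    return Om - Om.mean(axis=-1, keepdims=True)


def random_shape(rng, n, lo=0.3, hi=3.0):
    """A random positive alternative spectrum shape around the neutral 1/i."""
    return (1.0 / np.arange(1, n)) * rng.uniform(lo, hi, n - 1)
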