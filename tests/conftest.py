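import numpy as np
import pytest

from dfcomplexity import EmbeddingParams, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_sl_params():
    """Small embedding parameters that keep SL runs fast in tests."""
    return EmbeddingParams(m=3, L=1, w1=6, w2=206, p_ref=0.05)


@pytest.fixture
def white_recording(rng):
    """Two independent white-noise channels."""
    return Recording(rng.standard_normal((2, 1500)), fs=250.0)


def random_symmetric(rng, n, low=0.0, high=1.0):
    """Random symmetric weight matrix with zero diagonal."""
    w = rng.uniform(low, high, size=(n, n))
    w = np.triu(w, k=1)
    return w + w.T
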