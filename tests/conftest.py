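import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_data(rng):
    """Linearly separable 2-class toy set (3 sigma class separation)."""
    x = np.vstack([rng.normal(-1.5, 0.5, size=(50, 3)),
                   rng.normal(1.5, 0.5, size=(50, 3))])
    y = np.r_[-np.ones(50), np.ones(50)].astype(int)
    return x, y
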