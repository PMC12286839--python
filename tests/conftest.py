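import numpy as np
import pytest

from mothcompass.circstats import MeanVector


@pytest.fixture
def toy_vectors():
    """Fixed 5-vector set with distinct lengths (unambiguous ranks)."""
    alphas = [10.0, 25.0, 40.0, 355.0, 200.0]
    rs = [0.9, 0.7, 0.5, 0.95, 0.2]
    return [MeanVector(alpha=a, r=r, n=10) for a, r in zip(alphas, rs)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
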