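import numpy as np
import pytest

from cpoe.kernels import KernelSpec, SEard
from cpoe.synthetic import make_two_se_benchmark


@pytest.fixture(scope="session")
def two_se_small():
    """150-point planar GP draw with a long- and a short-lengthscale component."""
    return make_two_se_benchmark(N=150, D=2, seed=3)


@pytest.fixture(scope="session")
def two_se_medium():
    return make_two_se_benchmark(N=256, D=2, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def se1d():
    """Unit SE kernel in one dimension with sigma_n = 0.1."""
    return KernelSpec(terms=(SEard(lengthscales=np.array([1.0]), variance=1.0),),
                      noise_std=0.1, input_dim=1)
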