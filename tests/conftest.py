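import numpy as np
import pytest

from medfuse.network import NetConfig, init_weights
from medfuse.phantoms import PhantomSpec, make_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    return NetConfig.small()


@pytest.fixture(scope="session")
def small_weights(small_cfg):
    return init_weights(small_cfg, seed=7)


@pytest.fixture(scope="session")
def clean_pair():
    """Noiseless, lesion-free phantom pair with flat CT interior."""
    return make_pair(PhantomSpec(size=64, seed=3, noise_sd=0.0, n_lesions=0))


@pytest.fixture(scope="session")
def noisy_pair():
    return make_pair(PhantomSpec(size=64, seed=11))
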