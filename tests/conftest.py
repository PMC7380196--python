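import numpy as np
import pytest

from fluorex.synthetic_data import default_ground_truth


@pytest.fixture(scope="session")
def truth_noiseless():
    return default_ground_truth(noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def truth_noisy():
    return default_ground_truth(noise_sigma=0.01, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
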