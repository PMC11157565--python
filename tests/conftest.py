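import numpy as np
import pytest

from swarmselect import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """60 samples, 3 relevant + 3 redundant + 14 noise features."""
    return generate(SyntheticSpec(n_samples=60, n_relevant=3, n_redundant=3,
                                  n_noise=14, noise_sd=0.5, seed=7))
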