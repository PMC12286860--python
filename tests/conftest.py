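import numpy as np
import pytest

import neurocode as nc


@pytest.fixture(scope="session")
def extractor():
    return nc.ToyConvExtractor(seed=0, input_size=16, channels=(4, 8), dense_units=16)


@pytest.fixture(scope="session")
def small_world():
    """Tiny seeded stimulus world shared across fast tests."""
    return nc.make_stimulus_world(7, n_train=40, n_test=10, n_categories=6, image_size=32)


@pytest.fixture(scope="session")
def noiseless_subject(small_world):
    return nc.make_virtual_subject(11, small_world, n_voxels=60, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_subject(small_world):
    return nc.make_virtual_subject(12, small_world, n_voxels=60, noise_sd=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
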