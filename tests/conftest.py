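import numpy as np
import pytest

from histotune.preprocessing import partition_dataset
from histotune.search_space import build_default_space
from histotune.synthetic import SyntheticImageSpec, make_synthetic_imageset


@pytest.fixture(scope="session")
def space15():
    return build_default_space(include_augmentation=True)


@pytest.fixture(scope="session")
def space7():
    return build_default_space(include_augmentation=False)


@pytest.fixture(scope="session")
def small_imageset():
    """Separable two-class set of small images for fast backend tests."""
    spec = SyntheticImageSpec(n_per_class=(60, 60), size=(32, 32), separability=1.0, noise_sd=8.0, seed=11)
    return make_synthetic_imageset(spec)


@pytest.fixture(scope="session")
def small_split(small_imageset):
    return partition_dataset(small_imageset, ratio=0.85, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
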