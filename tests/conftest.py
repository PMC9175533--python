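import numpy as np
import pytest

from impa.search_space import default_space
from impa.synthetic import generate_image_dataset, stratified_split


@pytest.fixture(scope="session")
def space8():
    return default_space()


@pytest.fixture(scope="session")
def separable_imageset():
    """Small, clearly separable two-class image set shared across tests."""
    return generate_image_dataset(60, size=32, separation=5.0, seed=7)


@pytest.fixture(scope="session")
def separable_splits(separable_imageset):
    return stratified_split(separable_imageset, 0.25, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
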