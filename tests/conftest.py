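import numpy as np
import pytest

from neutrokd.preprocessing import PreprocessConfig
from neutrokd.synthetic import SyntheticSpec, generate, stratified_split


@pytest.fixture(scope="session")
def small_dataset():
    """35 retina-like images, 7 balanced classes, 64 px."""
    return generate(SyntheticSpec(n_classes=7, images_per_class=5, image_size=64, seed=11))


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return stratified_split(small_dataset, 0.2, seed=0)


@pytest.fixture(scope="session")
def pre64():
    return PreprocessConfig(target_size=64, augment=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distributions(rng, n, c):
    """Dirichlet-ish random probability vectors via normalized exponentials."""
    p = rng.exponential(1.0, size=(n, c))
    return p / p.sum(axis=1, keepdims=True)
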