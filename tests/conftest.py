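import numpy as np
import pytest

from blockcs import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_images():
    """Ten small synthetic images (deterministic), for codec-quality tests."""
    styles = list(fixtures.STYLES)
    return [
        fixtures.generate_class_image(styles[i % 4], size=64, seed=100 + i)
        for i in range(10)
    ]


@pytest.fixture(scope="session")
def toy_dataset():
    """A 10-image, 4-class dataset used for overfitting sanity checks."""
    spec = fixtures.FixtureSpec(images_per_class=3, image_size=64, seed=7)
    ds = fixtures.generate_dataset(spec)
    return ds.subset(list(range(10)))
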