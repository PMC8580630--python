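import numpy as np
import pytest

from dermelm.synthetic import benign_spec, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_lesion_image():
    """One deterministic 128x128 benign lesion image with its mask."""
    img, mask, label = generate_image(
        benign_spec(image_size=128), np.random.default_rng(1234)
    )
    return img, mask, label


@pytest.fixture(scope="session")
def toy_features():
    """Tiny two-class feature matrix: one informative column plus noise.

    Column 0 separates the classes perfectly; columns 1..9 are pure noise.
    """
    rng = np.random.default_rng(77)
    n = 120
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 10))
    X[:, 0] = y * 4.0 + rng.standard_normal(n) * 0.3
    return X, y
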