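import numpy as np
import pytest

from msld import FovMask, standard_suite


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_img32():
    """Seeded 32x32 random grayscale image in [0, 1]."""
    return np.random.default_rng(0).random((32, 32))


@pytest.fixture()
def disk_fov32():
    rr, cc = np.mgrid[0:32, 0:32]
    return FovMask((rr - 15.5) ** 2 + (cc - 15.5) ** 2 <= 14.0**2)


@pytest.fixture(scope="session")
def suite():
    """Noise-free standard phantom suite, seed 1."""
    return standard_suite(1)
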