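import numpy as np
import pytest

from hcwssc import HyperCube, SceneSpec, make_scene


@pytest.fixture
def rng():
    return np.random.RandomState(42)


def random_spectrum(rng, n_bands=12):
    """Strictly positive, non-constant random spectrum."""
    return rng.uniform(0.05, 1.0, n_bands)


@pytest.fixture
def small_cube(rng):
    """6 x 5 x 8 positive cube with two masked pixels."""
    data = rng.uniform(0.05, 1.0, size=(6, 5, 8))
    mask = np.ones((6, 5), dtype=bool)
    mask[0, 0] = mask[5, 4] = False
    wl = np.linspace(400.0, 1000.0, 8)
    return HyperCube(data=data, wavelengths=wl, mask=mask)


@pytest.fixture(scope="session")
def noisy_scene():
    """Moderate-noise 5-class scene at the default desk scale."""
    return make_scene(SceneSpec(seed=3))
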