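import numpy as np
import pytest

from mskseg.phantom import PhantomSpec, generate_phantom


SMALL_GRID = (16, 48, 48)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=SMALL_GRID, spacing_mm=(2.0, 1.0, 1.0), seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def bridged_phantom():
    spec = PhantomSpec(
        grid_shape=SMALL_GRID, spacing_mm=(2.0, 1.0, 1.0), bridge_prob=1.0, shape_jitter=0.0, seed=7
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def zero_noise_phantom():
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        hu_sd=0.0,
        noise_sd=0.0,
        shape_jitter=0.0,
        seed=5,
    )
    return spec, generate_phantom(spec)


def random_mask(rng: np.random.Generator, shape=(12, 12, 12), p=0.15) -> np.ndarray:
    """A connected-ish random blob: a few dilated seed points."""
    from scipy import ndimage

    m = rng.random(shape) < p
    m = ndimage.binary_dilation(m, iterations=1)
    return m
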