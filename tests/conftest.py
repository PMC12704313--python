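import numpy as np
import pytest

from shgcast.phantom import PhantomParams, generate_phantom


def small_params(**overrides) -> PhantomParams:
    """Desk-scale phantom parameters for fast unit tests: a 24x64x64 grid
    with two small glands, a narrow lumen and a thin myometrial frame."""
    base = dict(
        shape=(24, 64, 64),
        n_glands=2,
        gland_radius=(3.5, 5.0),
        gland_length=(12.0, 20.0),
        lobe_radius=(3.5, 5.0),
        lumen_halfwidth=7.0,
        myometrium_thickness=4.0,
        cage_thickness=2.5,
        cage_ratio=2.0,
        seed=0,
    )
    base.update(overrides)
    return PhantomParams(**base)


@pytest.fixture(scope="session")
def small_truth():
    return generate_phantom(small_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.3):
    return rng.random(shape) < p
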