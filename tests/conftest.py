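import numpy as np
import pytest

from ftdmorph import synthetic as syn


@pytest.fixture(scope="session")
def phantom():
    """Default desk-scale template (48^3 at 2 mm)."""
    return syn.make_template()


@pytest.fixture(scope="session")
def phantom_coarse():
    """Same anatomy rasterized at 32^3 / 3 mm for cheap tests."""
    return syn.make_template(syn.PhantomSpec(grid_shape=(32, 32, 32), spacing=(3.0, 3.0, 3.0)))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free template."""
    return syn.make_template(syn.PhantomSpec(noise_sd=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
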