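import numpy as np
import pytest

from pseudohe import OpticsConfig, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_optics():
    """Instrument defaults: f = 17.1 cycles/mm, 10X/0.45 NA, 630/470 nm LEDs."""
    return OpticsConfig()


@pytest.fixture
def small_spec():
    """A small, fast phantom for unit tests (full-size runs live in acceptance)."""
    return PhantomSpec(
        image_shape=(128, 128),
        n_nuclei=20,
        n_lumina=1,
        n_rows=1,
        n_cols=1,
        overlap_px=0,
        rng_seed=7,
    )
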