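import numpy as np
import pytest

from sedseg.phantom import PhantomConfig, generate_volume
from sedseg.sed1_unet import Sed1Config, build_sed1_model
from sedseg.sed2_dense_unet import Sed2Config, build_sed2_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A 6-slice, 64x64 phantom with at least one tumor."""
    cfg = PhantomConfig(grid=(64, 64), n_slices=6, tumor_count_range=(1, 2), seed=7)
    return generate_volume(cfg)


@pytest.fixture(scope="session")
def tiny_sed1():
    """Randomly initialized stage-1 model at reduced width (64x64 input)."""
    return build_sed1_model(Sed1Config(input_size=(64, 64, 1), base_channels=4), seed=0)


@pytest.fixture(scope="session")
def tiny_sed2():
    """Randomly initialized stage-2 model at reduced growth rate (64x64 input)."""
    return build_sed2_model(
        Sed2Config(input_size=(64, 64, 1), growth_rate=2, initial_conv_channels=6),
        seed=0,
    )
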