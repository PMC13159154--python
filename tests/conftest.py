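import numpy as np
import pytest

from chipstain import SimConfig
from chipstain.imagecore import Channel, ChipImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, clean simulation setup used across module tests."""
    return SimConfig(
        channel_width_px=160,
        channel_height_px=120,
        seeding_density=30,
        baseline_death_fraction=0.0,
        noise_sd=0.0,
        stain_unevenness_amplitude=0.0,
        seed=7,
    )


def make_image(pixels, channel=Channel.BF, **kw):
    return ChipImage(pixels=np.asarray(pixels), channel=channel, **kw)
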