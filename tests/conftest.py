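import numpy as np
import pytest

from polyqtc.imagequant import CalibratedImage
from polyqtc.simdata import ArraySimConfig, ImageSimConfig, gen_array_data, gen_image


@pytest.fixture(scope="session")
def detection_scene():
    """One synthetic image with several well-separated bright aggregates."""
    cfg = ImageSimConfig(seed=3)
    img, truth = gen_image(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def small_array_dataset():
    """A small probe-level dataset with no planted effects (null)."""
    cfg = ArraySimConfig(n_genes=60, seed=7)
    long, truth = gen_array_data(cfg)
    return cfg, long, truth


def flat_image(value: float = 0.0, shape=(64, 64), pixel_size: float = 0.1) -> CalibratedImage:
    return CalibratedImage(np.full(shape, float(value)), pixel_size)
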