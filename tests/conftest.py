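import numpy as np
import pytest

from funduseg.io_masks import CLASSES, FundusImage, LesionMaskSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(h=64, w=64, fill=0, source_id="x"):
    px = np.full((h, w, 3), fill, dtype=np.uint8)
    return FundusImage(px, source_id=source_id)


def make_masks(shape=(64, 64), source_id="x", **class_masks):
    masks = {cls: np.zeros(shape, dtype=np.uint8) for cls in CLASSES}
    for cls, m in class_masks.items():
        masks[cls] = np.asarray(m, dtype=np.uint8)
    return LesionMaskSet(masks, source_id=source_id)


@pytest.fixture
def disc_image():
    """A bright disc on black background, like a fundus field of view."""
    h, w = 80, 120
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (yy - 40) ** 2 + (xx - 60) ** 2 <= 30**2
    px = np.zeros((h, w, 3), dtype=np.uint8)
    px[disc] = (180, 90, 40)
    return FundusImage(px, source_id="disc")
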