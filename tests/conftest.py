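import numpy as np
import pytest

import mammotex as mx
from mammotex import features as fb
from mammotex.image import BreastMask, GrayImage


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve synthetic subjects with in-memory images (128x128, 0.05 cm/px)."""
    cfg = mx.CohortConfig(
        n_cases=8,
        n_controls=4,
        image_shape=(128, 128),
        pixel_spacing=0.05,
        seed=20,
        texture_effect=1.0,
    )
    return mx.generate_cohort(cfg)


@pytest.fixture(scope="session")
def sample_subject(small_cohort):
    return small_cohort[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_roi(rng, shape=(12, 12), n_levels=16, mask_density=0.85):
    """Random quantized ROI with a random mask, for brute-force oracles."""
    from mammotex.texture.statistical import QuantizedROI

    levels = rng.integers(0, n_levels, size=shape)
    mask = rng.random(shape) < mask_density
    if not mask.any():
        mask[0, 0] = True
    return QuantizedROI(levels=levels, mask=mask, spacing=0.02)


def disk_mask(radius=40, pad=8):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def as_image(arr, spacing=0.02):
    return GrayImage(np.asarray(arr, dtype=np.uint8), spacing)


def as_mask(arr):
    return BreastMask(np.asarray(arr, dtype=bool))
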