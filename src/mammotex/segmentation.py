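"""Four-step semiautomatic breast delineation.

The breast region on a digitized film mammogram is isolated by (1) blanking
near-white scanner stripes along the image border, (2) global Otsu
thresholding, (3) morphological opening with a disk, and (4) keeping the
largest connected foreground component (film labels and residual artifacts
are smaller than the breast and drop out).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .image import BreastMask, GrayImage

log = logging.getLogger(__name__)

NEAR_WHITE = 250


class DegenerateHistogramError(ValueError):
    """Raised when an image has a single gray value and cannot be thresholded."""


@dataclass(frozen=True)
class SegmentationConfig:
    margin_frac: float = 0.05
    bright_frac: float = 0.8
    opening_radius_px: int = 5
    connectivity: int = 8


def remove_border_stripes(
    image: GrayImage, margin_frac: float = 0.05, bright_frac: float = 0.8
) -> GrayImage:
    """Zero out near-white stripes hugging the image border.

    A full row (column) lying within ``margin_frac`` of the top/bottom
    (left/right) edge is blanked when more than ``bright_frac`` of its pixels
    are near-white (>= 250), the signature of scanner stripes on film.
    Interior pixels are never touched.
    """
    if not 0 < margin_frac <= 0.1:
        raise ValueError("margin_frac must lie in (0, 0.1]")
    v = image.values.copy()
    h, w = v.shape
    bright = image.values >= NEAR_WHITE
    mr = int(np.floor(margin_frac * h))
    mc = int(np.floor(margin_frac * w))
    for r in list(range(mr)) + list(range(h - mr, h)):
        if bright[r, :].mean() > bright_frac:
            v[r, :] = 0
    for c in list(range(mc)) + list(range(w - mc, w)):
        if bright[:, c].mean() > bright_frac:
            v[:, c] = 0
    return GrayImage(v, image.spacing)


def otsu_threshold(image: GrayImage) -> tuple[int, np.ndarray]:
    """Gray level t minimizing within-class intensity variance.

    Foreground is ``gray > t``. Equivalent to maximizing the between-class
    variance; computed over all 256 candidate levels from the histogram with
    cumulative sums, returning the smallest minimizer.
    """
    v = image.values
    hist = np.bincount(v.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram: single gray value")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                      # class {<= t}
    m0 = np.cumsum(hist * levels)
    w1 = n - w0
    m1 = m0[-1] - m0
    # within-class variance, guarding empty classes
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, m1 / w1, 0.0)
    s0 = np.cumsum(hist * levels**2)
    var0 = np.where(w0 > 0, s0 / np.maximum(w0, 1) - mu0**2, 0.0)
    var1 = np.where(w1 > 0, (s0[-1] - s0) / np.maximum(w1, 1) - mu1**2, 0.0)
    wcv = (w0 * var0 + w1 * var1) / n
    # only thresholds with both classes nonempty are admissible
    wcv[w1 == 0] = np.inf
    t = int(np.argmin(wcv))
    return t, v > t


def open_binary(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Morphological opening with a discrete disk structuring element."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    se = disk(radius_px)
    m = np.asarray(mask, dtype=bool)
    opened = ndi.binary_opening(m, structure=se)
    assert not np.any(opened & ~m), "opening added foreground pixels"
    return opened


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected foreground component.

    Area ties are broken in favor of the component containing the earliest
    foreground pixel in row-major scan order.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask: no foreground component")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndi.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndi.label(m, structure=structure)
    areas = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(areas == areas.max()) + 1
    if len(best) > 1:
        # scipy labels components in scan order, so the smallest label among
        # the maxima is the one whose first pixel comes first
        keep = int(best.min())
    else:
        keep = int(best[0])
    return labels == keep


def delineate_breast(
    image: GrayImage, config: SegmentationConfig | None = None
) -> BreastMask:
    """Run the four delineation steps in order and return the ROI mask."""
    cfg = config or SegmentationConfig()
    stripped = remove_border_stripes(image, cfg.margin_frac, cfg.bright_frac)
    _, binary = otsu_threshold(stripped)
    opened = open_binary(binary, cfg.opening_radius_px)
    breast = largest_component(opened, cfg.connectivity)
    if breast.sum() < 0.01 * breast.size:
        log.warning("delineated breast covers < 1%% of the image")
    return BreastMask(breast, provenance="automatic")
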