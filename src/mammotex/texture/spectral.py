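"""Wavelet subband-energy features.

The ROI's bounding-box crop (off-mask pixels replaced by the mean interior
gray value, so background content never leaks into the spectrum) is
decomposed by a 3-level 2-D pyramid for each of seven fixed wavelet bases;
the mean squared coefficient of each of the 10 subbands (approximation +
3 x {horizontal, vertical, diagonal}) is one feature, 70 in total.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..image import BreastMask, GrayImage

#: fixed basis set: a 2-tap, three 4-8 tap orthogonal, two symmetric
#: (least-asymmetric) and one biorthogonal family member
WAVELET_BASES = ("haar", "db2", "db4", "coif1", "sym2", "sym4", "bior2.2")
LEVELS = 3
#: subband names by the orientation of the spatial frequency they capture:
#: "h<level>" holds horizontal-frequency detail (variation along columns,
#: e.g. vertical stripes), "v<level>" vertical-frequency detail, "d" diagonal
SUBBAND_NAMES = ("a3",) + tuple(
    f"{b}{lv}" for lv in (3, 2, 1) for b in ("v", "h", "d")
)


def pyramid_energies(crop: np.ndarray, basis: str, levels: int = LEVELS) -> np.ndarray:
    """Mean squared coefficient of each subband of a 2-D pyramid decomposition.

    Order: deepest approximation, then (H, V, D) from the deepest level up to
    level 1 — 3*levels + 1 values.  Periodized boundary handling keeps
    orthonormal bases energy-conserving (Parseval).
    """
    crop = np.asarray(crop, dtype=np.float64)
    if min(crop.shape) < 2**levels:
        raise ValueError("crop too small for the requested decomposition depth")
    coeffs = pywt.wavedec2(crop, basis, level=levels, mode="periodization")
    out = [float(np.mean(coeffs[0] ** 2))]
    for detail in coeffs[1:]:
        for band in detail:
            out.append(float(np.mean(band**2)))
    return np.array(out)


def masked_crop(image: GrayImage, mask: BreastMask) -> np.ndarray:
    """Bounding-box crop with off-mask pixels filled by the mean interior gray."""
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = image.values[r0:r1, c0:c1].astype(np.float64)
    sub = m[r0:r1, c0:c1]
    fill = crop[sub].mean()
    crop[~sub] = fill
    return crop


def spectral_features70(image: GrayImage, mask: BreastMask) -> np.ndarray:
    """Subband energies for the seven pinned bases (7 x 10 values)."""
    crop = masked_crop(image, mask)
    return np.concatenate([pyramid_energies(crop, b) for b in WAVELET_BASES])
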