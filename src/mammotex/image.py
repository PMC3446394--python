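"""Core raster containers: 8-bit grayscale images and binary breast masks.

A mammogram surrogate is a 2-D grid of gray values in [0, 255] with a known
isotropic pixel spacing in cm/pixel; every downstream feature that carries a
physical unit (areas, perimeters, the 0.5 cm / 1.0 cm coarse grids) derives it
from that spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale image with isotropic pixel spacing (cm/pixel)."""

    values: np.ndarray
    spacing: float = 0.02

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("image must be 2-D")
        if v.dtype != np.uint8:
            if v.min() < 0 or v.max() > 255:
                raise ValueError("gray values must lie in [0, 255]")
            v = v.astype(np.uint8)
        if not self.spacing > 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def load(cls, path, spacing: float = 0.02) -> "GrayImage":
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
        return cls(arr, spacing)

    def save(self, path) -> None:
        Image.fromarray(self.values, mode="L").save(path)


@dataclass(frozen=True)
class BreastMask:
    """Binary region-of-interest mask aligned to a :class:`GrayImage`.

    ``provenance`` records whether the mask came out of the automatic
    delineation or was supplied externally after manual correction.
    """

    values: np.ndarray
    provenance: str = "automatic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values).astype(bool)
        if v.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.provenance not in ("automatic", "corrected"):
            raise ValueError("provenance must be 'automatic' or 'corrected'")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area_px(self) -> int:
        return int(self.values.sum())

    @classmethod
    def load(cls, path, provenance: str = "corrected") -> "BreastMask":
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr > 127, provenance)

    def save(self, path) -> None:
        Image.fromarray(self.values.astype(np.uint8) * 255, mode="L").save(path)
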