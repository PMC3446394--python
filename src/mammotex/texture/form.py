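"""Form-based features of the binary breast mask.

These describe only the shape of the delineated region: five shape scalars,
six normalized-radial-length (NRL) statistics, three Fourier-descriptor band
energies of the boundary, and the 72 moment features (NCM, Hu, Zernike) of
the mask treated as a 0/1 image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from ..image import BreastMask, GrayImage
from .moments import hu7, normalized_central_moments16, zernike49

SHAPE_NAMES = ("area", "perimeter", "compactness", "rectangularity", "circularity")
NRL_NAMES = ("mean", "sd", "entropy", "area_ratio", "zero_crossings", "roughness")
FD_NAMES = ("low_energy", "mid_energy", "high_energy")

# Moore neighborhood in clockwise order starting east
_MOORE = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


@dataclass(frozen=True)
class Contour:
    """Closed ordered outer boundary of a mask (pixel coordinates)."""

    points: np.ndarray          # (N, 2) array of (row, col), not repeated
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.points) < 8:
            raise ValueError("degenerate contour: fewer than 8 boundary points")


def trace_contour(mask: BreastMask | np.ndarray) -> Contour:
    """Moore-neighbor boundary trace of the mask's outer contour.

    Returns the ordered 8-connected boundary pixel sequence; the step lengths
    of this chain (1 or sqrt(2)) define the perimeter.
    """
    m = mask.values if isinstance(mask, BreastMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask")
    pad = np.pad(m, 1)
    rows, cols = np.nonzero(pad)
    start = (rows[0], cols[0])  # first foreground pixel in scan order
    points = [start]
    # backtrack: pixel we entered from; start came from the west
    prev_dir = 4  # index of west in _MOORE relative to current
    cur = start
    while True:
        found = False
        # search clockwise from the neighbor after the backtrack direction
        for k in range(1, 9):
            d = (prev_dir + k) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if pad[nr, nc]:
                nxt = (nr, nc)
                prev_dir = (d + 4) % 8
                found = True
                break
        if not found:  # isolated pixel
            break
        if nxt == start and len(points) > 1:
            break
        points.append(nxt)
        cur = nxt
    pts = np.array(points, dtype=np.float64) - 1.0  # undo padding
    r, c = np.nonzero(m)
    return Contour(points=pts, centroid=(float(r.mean()), float(c.mean())))


def _chain_perimeter(points: np.ndarray) -> float:
    diffs = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def _max_diameter(points: np.ndarray) -> float:
    if len(points) > 10:
        try:
            hull = ConvexHull(points)
            pts = points[hull.vertices]
        except Exception:
            pts = points
    else:
        pts = points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def shape_scalars5(mask: BreastMask, spacing: float) -> np.ndarray:
    """Area, perimeter, compactness, rectangularity, circularity.

    Area and perimeter carry physical units (cm^2 and cm); compactness is
    P^2/(4*pi*A), rectangularity the area fraction of the axis-aligned
    bounding box, circularity 4A/(pi*d_max^2) with d_max the maximal boundary
    diameter.
    """
    m = mask.values
    _, n_comp = ndi.label(m, structure=np.ones((3, 3), bool))
    if n_comp != 1:
        raise ValueError("mask must be a single connected component")
    contour = trace_contour(mask)
    area_px = float(m.sum())
    area = area_px * spacing**2
    perimeter = _chain_perimeter(contour.points) * spacing
    compactness = perimeter**2 / (4.0 * np.pi * area)
    rows, cols = np.nonzero(m)
    bbox_area = float((rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1))
    rectangularity = area_px / bbox_area
    d_max = _max_diameter(contour.points) * spacing
    circularity = 4.0 * area / (np.pi * d_max**2) if d_max > 0 else 0.0
    return np.array([area, perimeter, compactness, rectangularity, circularity])


def radial_length_features6(contour: Contour) -> np.ndarray:
    """Statistics of the normalized radial length r(k) = |p_k - centroid|/max.

    Mean, standard deviation, entropy of the 16-bin histogram of r, area
    ratio (fraction of boundary points with r above the mean), zero-crossing
    count of r - mean around the closed boundary, and roughness (mean
    absolute successive difference).
    """
    pts = contour.points
    c = np.asarray(contour.centroid)
    r = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    rmax = r.max()
    if rmax <= 0:
        raise ValueError("degenerate contour")
    r = r / rmax
    mean = float(r.mean())
    sd = float(r.std())
    hist, _ = np.histogram(r, bins=16, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    area_ratio = float((r > mean).mean())
    s = np.sign(r - mean)
    s = s[s != 0]
    zc = float(np.count_nonzero(s != np.roll(s, 1))) if len(s) else 0.0
    roughness = float(np.abs(np.diff(np.concatenate([r, r[:1]]))).mean())
    return np.array([mean, sd, entropy, area_ratio, zc, roughness])


def resample_contour(contour: Contour, n: int = 128) -> np.ndarray:
    """Arc-length resampling of the closed boundary to n equidistant points."""
    pts = np.vstack([contour.points, contour.points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ValueError("degenerate contour")
    t = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(t, arc, pts[:, 0])
    cols = np.interp(t, arc, pts[:, 1])
    return np.column_stack([rows, cols])


def fourier_descriptor_features3(contour: Contour) -> np.ndarray:
    """Normalized boundary-spectrum energies in low/mid/high frequency bands.

    The closed boundary, resampled to 128 points, is treated as a complex
    sequence; the DFT's c0 term is dropped (translation) and the spectrum is
    normalized by the fundamental max(|c_+1|, |c_-1|) (scale, robust to
    traversal orientation).  Features are the summed normalized energies for
    |k| in 2..5, 6..16 and 17..64.
    """
    n = 128
    pts = resample_contour(contour, n)
    z = pts[:, 1] + 1j * pts[:, 0]
    c = np.fft.fft(z) / n
    fundamental = max(abs(c[1]), abs(c[-1]))
    if fundamental <= 0:
        raise ValueError("degenerate contour")
    k = np.fft.fftfreq(n, d=1.0 / n).astype(int)
    absk = np.abs(k)
    absk[k == -n // 2] = n // 2
    e = (np.abs(c) / fundamental) ** 2
    low = float(e[(absk >= 2) & (absk <= 5)].sum())
    mid = float(e[(absk >= 6) & (absk <= 16)].sum())
    high = float(e[(absk >= 17) & (absk <= 64)].sum())
    return np.array([low, mid, high])


def binary_moment_features72(mask: BreastMask) -> np.ndarray:
    """NCM (16), Hu (7) and Zernike (49) moments of the 0/1 mask image."""
    img = GrayImage(mask.values.astype(np.uint8), spacing=1.0)
    ncm = normalized_central_moments16(img, mask)
    hu = hu7(ncm)
    zern = zernike49(img, mask)
    return np.concatenate([ncm, hu, zern])
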