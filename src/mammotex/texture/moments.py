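"""Moment-based features of the gray-level ROI.

Four central moments of the gray-value distribution, sixteen normalized
central moments (NCMs) of the intensity-weighted spatial distribution, the
seven Hu rotation invariants derived from the NCMs, and the magnitudes of the
49 Zernike moments up to radial order 12 on the unit disk circumscribing the
ROI bounding box.
"""

from __future__ import annotations

import math

import numpy as np

from ..image import BreastMask, GrayImage

NCM_ORDERS: tuple[tuple[int, int], ...] = tuple(
    (p, q) for p in range(4) for q in range(4)
)

#: Zernike (n, m) index pairs: n = 0..12, 0 <= m <= n, n - m even -> 49 pairs
ZERNIKE_INDICES: tuple[tuple[int, int], ...] = tuple(
    (n, m) for n in range(13) for m in range(n % 2, n + 1, 2)
)


def central_moments4(image: GrayImage, mask: BreastMask) -> np.ndarray:
    """Mean, variance, skewness and (non-excess) kurtosis of masked grays.

    Population moments; for a constant region skewness and kurtosis are 0 by
    convention.
    """
    vals = image.values[mask.values].astype(np.float64)
    if vals.size == 0:
        raise ValueError("empty mask")
    mean = vals.mean()
    var = float(((vals - mean) ** 2).mean())
    if var > 0:
        skew = float(((vals - mean) ** 3).mean()) / var**1.5
        kurt = float(((vals - mean) ** 4).mean()) / var**2
    else:
        skew = kurt = 0.0
    return np.array([mean, var, skew, kurt])


def _spatial_central_moments(intensity: np.ndarray, mask: np.ndarray, max_order: int):
    """Intensity-weighted spatial central moments mu_pq about the centroid."""
    rows, cols = np.nonzero(mask)
    f = intensity[rows, cols].astype(np.float64)
    m00 = f.sum()
    if m00 <= 0:
        raise ValueError("zero total intensity inside the mask")
    rc = (f @ rows) / m00
    cc = (f @ cols) / m00
    dr = rows - rc
    dc = cols - cc
    rp = np.vander(dr, max_order + 1, increasing=True)  # columns dr**p
    cp = np.vander(dc, max_order + 1, increasing=True)
    mu = np.einsum("k,kp,kq->pq", f, rp, cp)
    return mu, (rc, cc)


def normalized_central_moments16(image: GrayImage, mask: BreastMask) -> np.ndarray:
    """eta_pq = mu_pq / mu_00^(1+(p+q)/2) for p, q in {0..3}.

    By construction eta_00 = 1 and eta_10 = eta_01 = 0; these constants are
    carried in the catalog and removed downstream by zero-variance
    preselection.
    """
    mu, _ = _spatial_central_moments(image.values, mask.values, 3)
    return _eta_from_mu(mu)


def _eta_from_mu(mu: np.ndarray) -> np.ndarray:
    m00 = mu[0, 0]
    out = np.empty(len(NCM_ORDERS))
    for k, (p, q) in enumerate(NCM_ORDERS):
        if (p, q) == (0, 0):
            out[k] = 1.0
        elif (p, q) in ((1, 0), (0, 1)):
            # exactly zero about the centroid; snapping avoids floating-point
            # residue masquerading as a variable feature downstream
            out[k] = 0.0
        else:
            out[k] = mu[p, q] / m00 ** (1.0 + (p + q) / 2.0)
    return out


def hu7(ncm: np.ndarray) -> np.ndarray:
    """Hu's seven rotation-invariant combinations of the second/third NCMs."""
    eta = {pq: ncm[k] for k, pq in enumerate(NCM_ORDERS)}
    n20, n02, n11 = eta[(2, 0)], eta[(0, 2)], eta[(1, 1)]
    n30, n03 = eta[(3, 0)], eta[(0, 3)]
    n21, n12 = eta[(2, 1)], eta[(1, 2)]
    phi1 = n20 + n02
    phi2 = (n20 - n02) ** 2 + 4 * n11**2
    phi3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    phi4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    phi5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    phi6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    phi7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([phi1, phi2, phi3, phi4, phi5, phi6, phi7])


def _radial_poly_coeffs(n: int, m: int) -> np.ndarray:
    """Coefficients of rho**(n-2k) in the Zernike radial polynomial R_nm."""
    coeffs = np.zeros(13)  # powers of rho up to the maximum radial order 12
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        coeffs[n - 2 * k] = c
    return coeffs


_RADIAL_COEFFS = np.array(
    [_radial_poly_coeffs(n, m) for n, m in ZERNIKE_INDICES]
)


def zernike49(image: GrayImage, mask: BreastMask) -> np.ndarray:
    """Magnitudes |A_nm| for n = 0..12, n - m even.

    The support is the disk circumscribing the mask bounding box, centered at
    the intensity centroid; pixels outside the disk are ignored.
    """
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    rows, cols = np.nonzero(m)
    f = image.values[rows, cols].astype(np.float64)
    tot = f.sum()
    if tot <= 0:
        raise ValueError("zero total intensity inside the mask")
    rc = (f @ rows) / tot
    cc = (f @ cols) / tot
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    corners = np.array([[r0, c0], [r0, c1], [r1, c0], [r1, c1]], dtype=np.float64)
    radius = float(np.sqrt(((corners - [rc, cc]) ** 2).sum(axis=1)).max())
    if radius <= 0:
        raise ValueError("degenerate mask extent")
    rho = np.sqrt((rows - rc) ** 2 + (cols - cc) ** 2) / radius
    inside = rho <= 1.0
    rho = rho[inside]
    theta = np.arctan2(rows[inside] - rc, cols[inside] - cc)
    fv = f[inside]

    # powers of rho up to 12, shared across all (n, m)
    powers = np.vander(rho, 13, increasing=True)
    radial_all = powers @ _RADIAL_COEFFS.T          # (npix, 49)
    weighted = radial_all * fv[:, None]
    ang = np.outer(theta, np.arange(13))
    m_of = np.array([m for _, m in ZERNIKE_INDICES])
    k_idx = np.arange(len(ZERNIKE_INDICES))
    re = (weighted.T @ np.cos(ang))[k_idx, m_of]
    im = (weighted.T @ np.sin(ang))[k_idx, m_of]
    # pixel area in unit-disk coordinates is 1/radius^2
    n_of = np.array([n for n, _ in ZERNIKE_INDICES])
    return (n_of + 1) / np.pi * np.hypot(re, im) / radius**2
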