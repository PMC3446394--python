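"""First- and second-order gray-level statistics.

The 256 gray levels are quantized into G = 16 categories (level = gray // 16).
First-order features are the 16 relative bin frequencies.  Second-order
features come from a gray-level co-occurrence matrix (GLCM) and from Unser's
sum and difference histograms (SDH), both accumulated over the same pixel
pairs: unit displacement in the four directions 0°, 45°, 90°, 135°, both
orderings, restricted to pairs whose two endpoints lie inside the breast mask.
Pooling the four directions into a single matrix per scale yields
rotation-robust features.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from ..image import BreastMask, GrayImage

G = 16  # number of gray-level categories

#: unit displacements for 0, 45, 90, 135 degrees (row, col)
OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

SDH_DIRECT_NAMES = tuple(
    f"{h}_of_{s}"
    for h in ("sum", "difference")
    for s in ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")
)
SDH_NAMES = SDH_DIRECT_NAMES + tuple(f"unser_{n}" for n in HARALICK_NAMES)


@dataclass(frozen=True)
class QuantizedROI:
    """Gray levels quantized to [0, G-1], defined only on mask pixels."""

    levels: np.ndarray  # int array, garbage outside mask
    mask: np.ndarray    # bool array, same shape
    spacing: float

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SumDiffHistograms:
    """Normalized histograms of level sums (0..30) and differences (-15..15)."""

    sum_hist: np.ndarray   # length 2G-1, index s = i+j
    diff_hist: np.ndarray  # length 2G-1, index d+G-1 for d = i-j


def quantize(image: GrayImage, mask: BreastMask) -> QuantizedROI:
    """Map gray values to 16 categories (level = gray // 16) inside the mask."""
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    levels = (image.values.astype(np.int64) // G)
    return QuantizedROI(levels=levels, mask=m, spacing=image.spacing)


def histogram_features(roi: QuantizedROI) -> np.ndarray:
    """Relative frequency of each of the 16 gray-level categories."""
    if roi.n_valid == 0:
        raise ValueError("empty ROI")
    counts = np.bincount(roi.levels[roi.mask], minlength=G).astype(np.float64)
    return counts / counts.sum()


def _pair_levels(roi: QuantizedROI, offsets=OFFSETS):
    """Concatenated (a, b) level arrays over all valid pairs, one ordering."""
    a_all, b_all = [], []
    lv, m = roi.levels, roi.mask
    h, w = m.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        src = np.s_[r0:r1, c0:c1]
        dst = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = m[src] & m[dst]
        a_all.append(lv[src][valid])
        b_all.append(lv[dst][valid])
    return np.concatenate(a_all), np.concatenate(b_all)


def glcm_accumulate(roi: QuantizedROI, offsets=OFFSETS) -> np.ndarray:
    """Symmetric, normalized G x G co-occurrence matrix pooled over offsets."""
    if len(offsets) == 0:
        raise ValueError("offsets must be nonempty")
    a, b = _pair_levels(roi, offsets)
    if a.size == 0:
        raise ValueError("no valid pixel pairs inside the mask")
    counts = np.zeros((G, G), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    counts += counts.T  # accumulate both orderings
    return counts / counts.sum()


def sdh_accumulate(roi: QuantizedROI, offsets=OFFSETS) -> SumDiffHistograms:
    """Sum and difference histograms over the same symmetrized pairs."""
    if len(offsets) == 0:
        raise ValueError("offsets must be nonempty")
    a, b = _pair_levels(roi, offsets)
    if a.size == 0:
        raise ValueError("no valid pixel pairs inside the mask")
    s = np.bincount(a + b, minlength=2 * G - 1).astype(np.float64)
    d = np.bincount(a - b + (G - 1), minlength=2 * G - 1).astype(np.float64)
    d += d[::-1]  # both orderings: difference histogram symmetrized
    s *= 2.0      # keep sum histogram on the same pair count
    return SumDiffHistograms(sum_hist=s / s.sum(), diff_hist=d / d.sum())


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy2(p: np.ndarray) -> float:
    return float(-_xlog2x(p).sum())


def haralick13(P: np.ndarray) -> np.ndarray:
    """The 13 classical co-occurrence features of a normalized G x G GLCM.

    Fixed order: ASM, contrast, correlation, sum-of-squares variance, inverse
    difference moment, sum average, sum variance, sum entropy, entropy,
    difference variance, difference entropy, and the two information measures
    of correlation.  Logarithms are base 2 with 0*log0 = 0; sum variance is
    taken about the sum mean (not the sum entropy); the difference statistics
    use the absolute-difference histogram.  For a degenerate matrix confined
    to a single row/column, correlation is returned as 0 with a warning.
    """
    P = np.asarray(P, dtype=np.float64)
    i = np.arange(G, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # sum histogram p_{x+y}(k), k = 0..2G-2 and abs-difference p_{|x-y|}(k)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (ii + jj).astype(int), P)
    p_dabs = np.zeros(G)
    np.add.at(p_dabs, np.abs(ii - jj).astype(int), P)

    asm = float((P**2).sum())
    contrast = float((((ii - jj) ** 2) * P).sum())
    if var_x <= 0 or var_y <= 0:
        warnings.warn("degenerate GLCM: correlation undefined, returning 0")
        correlation = 0.0
    else:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    variance = float((((ii - mu_x) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())

    k_sum = np.arange(2 * G - 1, dtype=np.float64)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy2(p_sum)
    entropy = _entropy2(P.ravel())

    k_d = np.arange(G, dtype=np.float64)
    d_mean = float(k_d @ p_dabs)
    difference_variance = float(((k_d - d_mean) ** 2) @ p_dabs)
    difference_entropy = _entropy2(p_dabs)

    # information measures of correlation
    hxy = entropy
    pxy_outer = np.outer(px, py)
    nz = (P > 0) & (pxy_outer > 0)
    hxy1 = float(-(P[nz] * np.log2(pxy_outer[nz])).sum())
    hxy2 = _entropy2(pxy_outer.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def _moments_about_mean(p: np.ndarray, x: np.ndarray):
    mean = float(x @ p)
    var = float(((x - mean) ** 2) @ p)
    if var > 0:
        skew = float(((x - mean) ** 3) @ p) / var**1.5
        kurt = float(((x - mean) ** 4) @ p) / var**2
    else:
        skew = kurt = 0.0  # pinned convention for point-mass histograms
    return mean, var, skew, kurt


def sdh_features25(h: SumDiffHistograms) -> np.ndarray:
    """12 direct SDH statistics plus 13 Unser estimates of the GLCM features.

    Direct block: mean, variance, skewness, kurtosis, energy and entropy of
    the sum histogram and of the difference histogram.  Unser block: the 13
    co-occurrence features estimated from the two histograms alone.  Most have
    exact closed forms for symmetric accumulation (contrast, correlation,
    variance, IDM, the sum/difference statistics); ASM and entropy use Unser's
    independence approximation, and the two information measures are computed
    on the normalized product-form joint estimate Ps(i+j)Pd(i-j).
    """
    ps, pd = h.sum_hist, h.diff_hist
    s_vals = np.arange(2 * G - 1, dtype=np.float64)        # s = i + j
    d_vals = s_vals - (G - 1)                              # d = i - j

    direct = []
    for p, x in ((ps, s_vals), (pd, d_vals)):
        mean, var, skew, kurt = _moments_about_mean(p, x)
        direct += [mean, var, skew, kurt, float((p**2).sum()), _entropy2(p)]

    mu_s = float(s_vals @ ps)
    v_s = float(((s_vals - mu_s) ** 2) @ ps)
    v_d = float((d_vals**2) @ pd)

    asm_est = float((ps**2).sum() * (pd**2).sum())
    contrast = v_d
    correlation = (v_s - v_d) / (v_s + v_d) if (v_s + v_d) > 0 else 0.0
    variance = (v_s + v_d) / 4.0
    idm = float((pd / (1.0 + d_vals**2)).sum())
    sum_average = mu_s
    sum_variance = v_s
    sum_entropy = _entropy2(ps)
    entropy_est = _entropy2(ps) + _entropy2(pd)
    # fold the signed difference histogram to |d|
    p_dabs = pd[G - 1 :].copy()
    p_dabs[1:] += pd[: G - 1][::-1]
    k_d = np.arange(G, dtype=np.float64)
    d_mean = float(k_d @ p_dabs)
    difference_variance = float(((k_d - d_mean) ** 2) @ p_dabs)
    difference_entropy = _entropy2(p_dabs)

    # product-form joint estimate for the information measures
    S, D = np.meshgrid(s_vals, d_vals, indexing="ij")
    valid = ((S + D) % 2 == 0) & (S + D >= 0) & (S + D <= 2 * (G - 1)) \
        & (S - D >= 0) & (S - D <= 2 * (G - 1))
    joint = np.zeros((G, G))
    w = np.outer(ps, pd)
    si, di = np.nonzero(valid)
    ii = ((si + (di - (G - 1))) // 2).astype(int)
    jj = ((si - (di - (G - 1))) // 2).astype(int)
    np.add.at(joint, (ii, jj), w[si, di])
    tot = joint.sum()
    if tot > 0:
        joint /= tot
        est = haralick13(joint)
        imc1, imc2 = float(est[11]), float(est[12])
    else:
        imc1 = imc2 = 0.0

    unser = [
        asm_est,
        contrast,
        correlation,
        variance,
        idm,
        sum_average,
        sum_variance,
        sum_entropy,
        entropy_est,
        difference_variance,
        difference_entropy,
        imc1,
        imc2,
    ]
    return np.array(direct + unser)
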