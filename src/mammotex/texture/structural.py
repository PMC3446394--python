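"""Structural microtexture features.

Statistical-geometrical features (SGF) summarize the number and irregularity
of connected regions across the stack of threshold binarizations of the
16-level ROI; run-length features summarize maximal runs of constant gray
level along the four principal directions.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .statistical import G, QuantizedROI

SGF_NAMES = tuple(
    f"{curve}_{stat}"
    for curve in ("noc1", "noc0", "irgl1", "irgl0")
    for stat in ("max", "average", "mean", "sd")
)

RL_STAT_NAMES = ("sre", "lre", "gln", "rln", "rp")
RL_DIRECTIONS = ("0", "45", "90", "135")
RL_NAMES = tuple(f"{s}_d{d}" for d in RL_DIRECTIONS for s in RL_STAT_NAMES)

_EIGHT = np.ones((3, 3), dtype=bool)


def _region_stats(binary: np.ndarray) -> tuple[int, float]:
    """Region count and area-weighted mean irregularity of a binary image.

    Irregularity of a region follows Chen: (1 + sqrt(pi) * d_max) / sqrt(A) - 1
    with d_max the largest centroid-to-pixel distance, zero for a disk in the
    continuum limit.
    """
    labels, n = ndi.label(binary, structure=_EIGHT)
    if n == 0:
        return 0, 0.0
    rows, cols = np.nonzero(binary)
    lab = labels[rows, cols]
    areas = np.bincount(lab, minlength=n + 1)[1:].astype(np.float64)
    rc = np.bincount(lab, weights=rows, minlength=n + 1)[1:] / areas
    cc = np.bincount(lab, weights=cols, minlength=n + 1)[1:] / areas
    d = np.hypot(rows - rc[lab - 1], cols - cc[lab - 1])
    dmax = np.zeros(n)
    np.maximum.at(dmax, lab - 1, d)
    irgl = (1.0 + np.sqrt(np.pi) * dmax) / np.sqrt(areas) - 1.0
    return n, float((areas * irgl).sum() / areas.sum())


def _curve_stats(g: np.ndarray) -> list[float]:
    """Max, plain average, and curve-weighted sample mean/SD over alpha."""
    alphas = np.arange(1, G, dtype=np.float64)
    mx = float(g.max())
    avg = float(g.mean())
    tot = g.sum()
    if tot > 0:
        mean = float((alphas * g).sum() / tot)
        sd = float(np.sqrt(((alphas - mean) ** 2 * g).sum() / tot))
    else:
        mean = sd = 0.0
    return [mx, avg, mean, sd]


def sgf16(roi: QuantizedROI) -> np.ndarray:
    """Chen's 16 statistical-geometrical features.

    For each threshold alpha = 1..15 the ROI is binarized (level >= alpha);
    the region count and mean irregularity of the foreground and of the
    within-mask complement form four curves over alpha, each summarized by
    four statistics.
    """
    if roi.n_valid == 0:
        raise ValueError("empty ROI")
    # crop to the mask bounding box; connectivity is unaffected
    rows, cols = np.nonzero(roi.mask)
    sl = np.s_[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]
    lv, m = roi.levels[sl], roi.mask[sl]
    noc1 = np.empty(G - 1)
    noc0 = np.empty(G - 1)
    irgl1 = np.empty(G - 1)
    irgl0 = np.empty(G - 1)
    for idx, alpha in enumerate(range(1, G)):
        b = (lv >= alpha) & m
        noc1[idx], irgl1[idx] = _region_stats(b)
        noc0[idx], irgl0[idx] = _region_stats(~b & m)
    out = []
    for curve in (noc1, noc0, irgl1, irgl0):
        out.extend(_curve_stats(curve))
    return np.array(out)


def _scan_lines(roi: QuantizedROI, direction: str):
    """Yield (levels, valid) 1-D arrays for each scan line of a direction."""
    lv, m = roi.levels, roi.mask
    h, w = m.shape
    if direction == "0":
        for r in range(h):
            yield lv[r], m[r]
    elif direction == "90":
        for c in range(w):
            yield lv[:, c], m[:, c]
    elif direction == "45":  # up-right diagonals of the flipped image
        flipped_lv, flipped_m = lv[::-1], m[::-1]
        for off in range(-h + 1, w):
            yield flipped_lv.diagonal(off), flipped_m.diagonal(off)
    elif direction == "135":
        for off in range(-h + 1, w):
            yield lv.diagonal(off), m.diagonal(off)
    else:
        raise ValueError(f"unknown direction {direction!r}")


def runlength_matrix(roi: QuantizedROI, direction: str) -> np.ndarray:
    """Counts of maximal constant-level runs, indexed (level, length - 1).

    Runs are confined to the mask: a run ends where the mask ends or the
    level changes.
    """
    if roi.n_valid == 0:
        raise ValueError("empty ROI")
    max_len = max(roi.mask.shape)
    counts = np.zeros((G, max_len), dtype=np.float64)
    # concatenate all scan lines with an invalid sentinel between them
    chunks = []
    for levels, valid in _scan_lines(roi, direction):
        seq = np.where(valid, levels, -1)
        chunks.append(seq)
        chunks.append([-1])
    seq = np.concatenate(chunks)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(seq) - 1]])
    lengths = ends - starts + 1
    values = seq[starts]
    keep = values >= 0
    np.add.at(counts, (values[keep], lengths[keep] - 1), 1.0)
    return counts


def runlength_features20(roi: QuantizedROI) -> np.ndarray:
    """Galloway's five run-length statistics for each of the four directions.

    Short-run emphasis, long-run emphasis, gray-level nonuniformity,
    run-length nonuniformity and run percentage, in direction order
    0, 45, 90, 135 degrees.
    """
    out = []
    for direction in RL_DIRECTIONS:
        rlm = runlength_matrix(roi, direction)
        j = np.arange(1, rlm.shape[1] + 1, dtype=np.float64)
        n_runs = rlm.sum()
        n_pix = float((rlm * j).sum())
        per_len = rlm.sum(axis=0)
        per_lvl = rlm.sum(axis=1)
        sre = float((per_len / j**2).sum() / n_runs)
        lre = float((per_len * j**2).sum() / n_runs)
        gln = float((per_lvl**2).sum() / n_runs)
        rln = float((per_len**2).sum() / n_runs)
        rp = n_runs / n_pix
        out.extend([sre, lre, gln, rln, rp])
    return np.array(out)
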