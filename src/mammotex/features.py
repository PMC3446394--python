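"""Feature catalog and extraction orchestration.

The canonical catalog enumerates all 470 features in a fixed order: the five
groups in the order moment, form, statistical, structural, spectral; within a
group by family; within a multiscale family by scale (full resolution, then
0.5 cm, then 1.0 cm blocks); then by formula order.  Only the co-occurrence,
sum/difference-histogram, statistical-geometrical and run-length families are
multiscale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import BreastMask, GrayImage
from .texture import form, moments, spectral, statistical, structural
from .texture.statistical import G, QuantizedROI

SCALES = ("full", "0.5cm", "1.0cm")
GROUPS = ("moment", "form", "statistical", "structural", "spectral")


@dataclass(frozen=True)
class FeatureDescriptor:
    feature_id: str
    group: str
    scale: str
    ordinal: int  # 1-based position in the canonical 470-vector


def _moment_ids():
    ids = [f"moment.cm.{n}" for n in ("mean", "variance", "skewness", "kurtosis")]
    ids += [f"moment.ncm.eta{p}{q}" for p, q in moments.NCM_ORDERS]
    ids += [f"moment.hu.phi{i}" for i in range(1, 8)]
    ids += [f"moment.zernike.z{n}_{m}" for n, m in moments.ZERNIKE_INDICES]
    return ids


def _form_ids():
    ids = [f"form.shape.{n}" for n in form.SHAPE_NAMES]
    ids += [f"form.nrl.{n}" for n in form.NRL_NAMES]
    ids += [f"form.fd.{n}" for n in form.FD_NAMES]
    ids += [f"form.binmom.ncm.eta{p}{q}" for p, q in moments.NCM_ORDERS]
    ids += [f"form.binmom.hu.phi{i}" for i in range(1, 8)]
    ids += [f"form.binmom.zernike.z{n}_{m}" for n, m in moments.ZERNIKE_INDICES]
    return ids


def _statistical_ids():
    ids = [(f"stat.hist.bin{i:02d}", "full") for i in range(1, G + 1)]
    for scale in SCALES:
        ids += [(f"stat.glcm.{n}@{scale}", scale) for n in statistical.HARALICK_NAMES]
    for scale in SCALES:
        ids += [(f"stat.sdh.{n}@{scale}", scale) for n in statistical.SDH_NAMES]
    return ids


def _structural_ids():
    ids = []
    for scale in SCALES:
        ids += [(f"struct.sgf.{n}@{scale}", scale) for n in structural.SGF_NAMES]
    for scale in SCALES:
        ids += [(f"struct.rl.{n}@{scale}", scale) for n in structural.RL_NAMES]
    return ids


def _spectral_ids():
    return [
        f"spec.{b}.{s}" for b in spectral.WAVELET_BASES for s in spectral.SUBBAND_NAMES
    ]


def catalog() -> list[FeatureDescriptor]:
    """Deterministic enumeration of the 470 feature descriptors."""
    entries: list[tuple[str, str, str]] = []
    entries += [(fid, "moment", "full") for fid in _moment_ids()]
    entries += [(fid, "form", "full") for fid in _form_ids()]
    entries += [(fid, "statistical", s) for fid, s in _statistical_ids()]
    entries += [(fid, "structural", s) for fid, s in _structural_ids()]
    entries += [(fid, "spectral", "full") for fid in _spectral_ids()]
    return [
        FeatureDescriptor(fid, grp, scale, i + 1)
        for i, (fid, grp, scale) in enumerate(entries)
    ]


def feature_ids() -> list[str]:
    return [d.feature_id for d in catalog()]


def group_counts() -> dict[str, int]:
    counts: dict[str, int] = {g: 0 for g in GROUPS}
    for d in catalog():
        counts[d.group] += 1
    return counts


def downscale(image: GrayImage, mask: BreastMask, target_cm: float) -> QuantizedROI:
    """Block-mean coarse ROI at 0.5 or 1.0 cm, re-quantized to 16 levels.

    Blocks are non-overlapping ``target_cm``-sized squares anchored at the
    image origin; a block enters the coarse mask when at least half of its
    pixels are inside the breast, and its value is the mean gray of those
    in-mask pixels.
    """
    factor_f = target_cm / image.spacing
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-6 or factor < 1:
        raise ValueError(
            f"target {target_cm} cm is not an integer multiple of the "
            f"pixel spacing {image.spacing}"
        )
    h, w = image.shape
    hb, wb = h // factor, w // factor
    if hb == 0 or wb == 0:
        raise ValueError("image smaller than one block")
    v = image.values[: hb * factor, : wb * factor].astype(np.float64)
    m = mask.values[: hb * factor, : wb * factor]
    v4 = v.reshape(hb, factor, wb, factor)
    m4 = m.reshape(hb, factor, wb, factor)
    cover = m4.sum(axis=(1, 3)) / factor**2
    valid = cover >= 0.5
    if not valid.any():
        raise ValueError("no block reaches 50% mask coverage")
    msum = np.maximum(m4.sum(axis=(1, 3)), 1)
    means = (v4 * m4).sum(axis=(1, 3)) / msum
    levels = np.minimum((means // G).astype(np.int64), G - 1)
    return QuantizedROI(levels=levels, mask=valid, spacing=target_cm)


def extract_all(image: GrayImage, mask: BreastMask) -> np.ndarray:
    """Evaluate all five families at their scales; 470 values in catalog order."""
    rois = {"full": statistical.quantize(image, mask)}
    for scale, cm in (("0.5cm", 0.5), ("1.0cm", 1.0)):
        rois[scale] = downscale(image, mask, cm)

    out: list[np.ndarray] = []
    # moment group
    ncm = moments.normalized_central_moments16(image, mask)
    out += [
        moments.central_moments4(image, mask),
        ncm,
        moments.hu7(ncm),
        moments.zernike49(image, mask),
    ]
    # form group
    contour = form.trace_contour(mask)
    out += [
        form.shape_scalars5(mask, image.spacing),
        form.radial_length_features6(contour),
        form.fourier_descriptor_features3(contour),
        form.binary_moment_features72(mask),
    ]
    # statistical group
    out.append(statistical.histogram_features(rois["full"]))
    glcms = {s: statistical.glcm_accumulate(rois[s]) for s in SCALES}
    out += [statistical.haralick13(glcms[s]) for s in SCALES]
    out += [
        statistical.sdh_features25(statistical.sdh_accumulate(rois[s])) for s in SCALES
    ]
    # structural group
    out += [structural.sgf16(rois[s]) for s in SCALES]
    out += [structural.runlength_features20(rois[s]) for s in SCALES]
    # spectral group
    out.append(spectral.spectral_features70(image, mask))

    vec = np.concatenate(out)
    if vec.shape[0] != len(feature_ids()):
        raise RuntimeError("feature vector length does not match the catalog")
    return vec


def extract_table(
    subjects,
    spacing: float | None = None,
) -> pd.DataFrame:
    """Feature table for an iterable of subjects.

    Each subject must expose ``subject_id`` plus either in-memory ``image``
    and ``mask`` attributes or an ``image_path``/``mask_path`` pair.
    """
    ids = feature_ids()
    rows = []
    index = []
    for s in subjects:
        if getattr(s, "image", None) is not None:
            img, msk = s.image, s.mask
        else:
            img = GrayImage.load(s.image_path, spacing or 0.02)
            msk = BreastMask.load(s.mask_path)
        rows.append(extract_all(img, msk))
        index.append(s.subject_id)
    df = pd.DataFrame(rows, columns=ids)
    df.insert(0, "subject_id", index)
    return df
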