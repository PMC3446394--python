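"""Synthetic mammogram-like images and a matched case-control cohort.

The generator emulates the statistical structure the analysis assumes rather
than mammographic anatomy: a bright, roughly half-elliptical breast region
attached to the left image edge on a dark background, optional near-white
scanner stripes and a film-label blob, and an interior made of a smooth
low-frequency "fatty" field plus brighter dense-tissue blobs occupying a
controllable fraction of the breast area.  Case status shifts two
second-order texture parameters — dense-blob edge contrast and the fatty
field's correlation length — by a configurable effect size ``texture_effect``
(in units of the parameter's between-subject SD), leaving a signal that is
partly orthogonal to the dense-area fraction.

Covariates are drawn per arm with defaults mirroring a 2:1 age-matched
case-control study of breast cancer; matched triplets (two cases, one
control) share a 10-year age decade.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .image import BreastMask, GrayImage

PARITY_CLASSES = ("0", "1-2", ">=3")

#: between-subject distribution of the dense-blob edge contrast (gray levels)
CONTRAST_MEAN, CONTRAST_SD = 35.0, 5.0
#: between-subject distribution of the fatty-field correlation length (px at
#: the default 0.02 cm/px spacing; scaled with spacing so the physical
#: correlation length is spacing-independent)
CORRLEN_MEAN_CM, CORRLEN_SD_CM = 0.08, 0.016


#: screening-plausible age range; matched decades are intersected with it
AGE_MIN, AGE_MAX = 25.0, 90.0


class MatchingError(ValueError):
    """Raised when an age decade cannot be populated for matched sets."""


@dataclass(frozen=True)
class CohortConfig:
    """Study design and generator parameters; defaults follow the emulated
    2:1 matched case-control population."""

    n_cases: int = 864
    n_controls: int = 432
    match_ratio: int = 2
    age_mean_sd: dict = field(
        default_factory=lambda: {"case": (57.5, 10.8), "control": (57.3, 10.6)}
    )
    bmi_mean_sd: dict = field(
        default_factory=lambda: {"case": (26.1, 5.0), "control": (24.6, 3.8)}
    )
    parity_probs: dict = field(
        default_factory=lambda: {
            "case": (0.155, 0.627, 0.218),
            "control": (0.143, 0.534, 0.323),
        }
    )
    fam_history_prob: dict = field(
        default_factory=lambda: {"case": 0.144, "control": 0.197}
    )
    age_ftp_mean_sd: dict = field(
        default_factory=lambda: {"case": (25.2, 4.6), "control": (25.6, 4.4)}
    )
    hrt_prob: dict = field(default_factory=lambda: {"case": 0.298, "control": 0.575})
    texture_effect: float = 1.0
    density_fraction_range: tuple[float, float] = (0.05, 0.40)
    image_shape: tuple[int, int] = (512, 400)
    pixel_spacing: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_effect < 0:
            raise ValueError("texture_effect must be >= 0")
        for arm in ("case", "control"):
            p = self.parity_probs[arm]
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"parity_probs[{arm}] must sum to 1")
            for prob in (self.fam_history_prob[arm], self.hrt_prob[arm], *p):
                if not 0.0 <= prob <= 1.0:
                    raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.density_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("density_fraction_range must be within [0, 1]")
        if self.n_cases != self.match_ratio * self.n_controls:
            raise ValueError(
                "exact matching requires n_cases = match_ratio * n_controls"
            )


@dataclass
class SyntheticSubject:
    subject_id: str
    label: str  # "case" | "control"
    matched_set_id: str
    age: float
    bmi: float
    parity_class: str
    family_history: str  # "yes" | "no"
    age_ftp: float
    hrt_ever: str
    pmd_true: float  # percent, achieved dense-area fraction * 100
    image_path: str = ""
    mask_true: BreastMask | None = None
    image: GrayImage | None = None
    dense_mask: np.ndarray | None = None
    texture_contrast: float = float("nan")
    texture_corr_length: float = float("nan")
    image_seed: int | None = None

    @property
    def mask(self) -> BreastMask | None:
        return self.mask_true


@dataclass(frozen=True)
class ImageParams:
    """Per-subject inputs to :func:`generate_image`."""

    image_shape: tuple[int, int]
    pixel_spacing: float
    pmd_target: float  # dense-area fraction in [0, 1]
    contrast: float
    corr_length_px: float
    add_stripes: bool = True
    add_label: bool = True


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=2000, context=""):
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x < hi:
            return x
    raise MatchingError(
        f"cannot draw a value in [{lo}, {hi}) from N({mean}, {sd}){context}"
    )


def generate_image(params: ImageParams, seed: int):
    """One mammogram surrogate with its ground truth.

    Returns ``(image, mask, dense_mask, pmd_achieved)`` where ``pmd_achieved``
    is the realized dense-area fraction (percent of breast area).
    """
    rng = np.random.default_rng(seed)
    h, w = params.image_shape
    if h < 128 or w < 128:
        raise ValueError("image_shape must be at least 128 x 128")
    if params.pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")

    # half-elliptical breast attached to the left edge, harmonic boundary
    rc = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    a = rng.uniform(0.30, 0.38) * h   # row semi-axis
    b = rng.uniform(0.50, 0.62) * w   # col semi-axis
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    dr = (rows - rc) / a
    dc = cols / b
    theta = np.arctan2(dr, dc)
    eps = rng.uniform(0.0, 0.025, size=3)
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    wobble = 1.0 + sum(
        e * np.cos(k * theta + ph) for k, e, ph in zip((2, 3, 4), eps, phases)
    )
    breast = dr**2 + dc**2 <= wobble**2
    edges_touched = sum(
        arr.any() for arr in (breast[0, :], breast[-1, :], breast[:, 0], breast[:, -1])
    )
    if edges_touched >= 4:
        raise ValueError("breast region touches all four image edges")

    # smooth fatty field with subject-specific correlation length
    noise = rng.normal(0.0, 1.0, size=(h, w))
    fat = ndi.gaussian_filter(noise, sigma=max(params.corr_length_px, 0.5))
    fat_sd = fat.std()
    if fat_sd > 0:
        fat = fat / fat_sd * 15.0
    img = np.full((h, w), 4.0)
    img += rng.normal(0.0, 2.0, size=(h, w))
    img[breast] = 110.0 + fat[breast]

    # dense blobs up to the target area fraction, edge height = contrast
    breast_area = int(breast.sum())
    dense = np.zeros((h, w), dtype=bool)
    target_px = params.pmd_target * breast_area
    if target_px > 0:
        br_rows, br_cols = np.nonzero(breast)
        min_ax = min(a, b)
        for _ in range(4000):
            if dense.sum() >= target_px:
                break
            k = rng.integers(len(br_rows))
            cr, ccl = br_rows[k], br_cols[k]
            rad = rng.uniform(0.04, 0.10) * min_ax
            rr = (rows - cr) / rad
            cc = (cols - ccl) / (rad * rng.uniform(0.7, 1.3))
            blob = (rr**2 + cc**2 <= 1.0) & breast
            dense |= blob
        # soft-edged intensity bump: profile decays over ~2 px at the rim
        dist_in = ndi.distance_transform_edt(dense)
        profile = np.clip(dist_in / 2.0, 0.0, 1.0)
        img += params.contrast * profile

    pmd_achieved = 100.0 * dense.sum() / breast_area

    if params.add_stripes:
        sw = max(2, int(0.01 * w))
        img[:, w - sw :] = 255.0       # right-edge scanner stripe
        img[: max(2, int(0.01 * h)), :] = 255.0  # top-edge stripe
    if params.add_label:
        lr = int(0.12 * h)
        lc = int(0.88 * w)
        half = max(4, int(0.02 * h))
        if not breast[lr - half : lr + half, lc - half : lc + half].any():
            img[lr - half : lr + half, lc - half : lc + half] = 220.0

    image = GrayImage(np.clip(img, 0, 255).astype(np.uint8), params.pixel_spacing)
    return image, BreastMask(breast, "automatic"), dense, pmd_achieved


def _draw_covariates(rng, cfg: CohortConfig, arm: str, age: float) -> dict:
    return {
        "age": age,
        "bmi": rng.normal(*cfg.bmi_mean_sd[arm]),
        "parity_class": PARITY_CLASSES[
            rng.choice(3, p=np.asarray(cfg.parity_probs[arm]) / sum(cfg.parity_probs[arm]))
        ],
        "family_history": "yes" if rng.random() < cfg.fam_history_prob[arm] else "no",
        "age_ftp": rng.normal(*cfg.age_ftp_mean_sd[arm]),
        "hrt_ever": "yes" if rng.random() < cfg.hrt_prob[arm] else "no",
    }


def _texture_params(rng, cfg: CohortConfig, arm: str, spacing: float):
    delta = cfg.texture_effect if arm == "case" else 0.0
    contrast = rng.normal(CONTRAST_MEAN + delta * CONTRAST_SD, CONTRAST_SD)
    corr_cm = rng.normal(
        CORRLEN_MEAN_CM + delta * CORRLEN_SD_CM, CORRLEN_SD_CM
    )
    corr_px = max(corr_cm, 0.01) / spacing
    return float(np.clip(contrast, 5.0, 120.0)), float(corr_px)


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    images: bool = True,
) -> list[SyntheticSubject]:
    """Matched case-control cohort with per-subject images and ground truth.

    Matched sets are built constructively: each control's age fixes a 10-year
    decade, and the ``match_ratio`` case ages of its set are drawn from the
    case-arm age distribution truncated to that decade.  With ``images=False``
    only covariates and texture parameters are generated (no rasters), which
    is enough for distributional checks.  When ``out_dir`` is given, images
    and ground-truth masks are written as 8-bit PNGs.
    """
    ss = np.random.SeedSequence(config.seed)
    cov_ss, tex_ss, img_ss = ss.spawn(3)
    rng_cov = np.random.default_rng(cov_ss)
    rng_tex = np.random.default_rng(tex_ss)
    image_seeds = img_ss.generate_state(config.n_cases + config.n_controls)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    subjects: list[SyntheticSubject] = []
    sid = 0
    dens_lo, dens_hi = config.density_fraction_range
    for set_idx in range(config.n_controls):
        set_id = f"set{set_idx:04d}"
        # ages confined to a screening-plausible range so every decade a
        # control can land in carries case-arm probability mass
        ctrl_age = _truncated_normal(
            rng_cov, *config.age_mean_sd["control"], AGE_MIN, AGE_MAX
        )
        decade = int(ctrl_age // 10)
        age_lo = max(10.0 * decade, AGE_MIN)
        age_hi = min(10.0 * (decade + 1), AGE_MAX)
        ages = [ctrl_age]
        for _ in range(config.match_ratio):
            ages.append(
                _truncated_normal(
                    rng_cov,
                    *config.age_mean_sd["case"],
                    age_lo,
                    age_hi,
                    context=f" for age decade {decade}0-{decade}9 in {set_id}",
                )
            )
        arms = ["control"] + ["case"] * config.match_ratio
        for arm, age in zip(arms, ages):
            cov = _draw_covariates(rng_cov, config, arm, age)
            contrast, corr_px = _texture_params(
                rng_tex, config, arm, config.pixel_spacing
            )
            pmd_target = rng_tex.uniform(dens_lo, dens_hi)
            subj = SyntheticSubject(
                subject_id=f"S{sid:05d}",
                label=arm,
                matched_set_id=set_id,
                pmd_true=100.0 * pmd_target,
                texture_contrast=contrast,
                texture_corr_length=corr_px,
                image_seed=int(image_seeds[sid]),
                **cov,
            )
            if images:
                params = ImageParams(
                    image_shape=config.image_shape,
                    pixel_spacing=config.pixel_spacing,
                    pmd_target=pmd_target,
                    contrast=contrast,
                    corr_length_px=corr_px,
                )
                img, mask, dense, pmd = generate_image(params, subj.image_seed)
                subj.image = img
                subj.mask_true = mask
                subj.dense_mask = dense
                subj.pmd_true = pmd
                if out_path is not None:
                    ip = out_path / f"{subj.subject_id}.png"
                    mp = out_path / f"{subj.subject_id}_mask.png"
                    img.save(ip)
                    mask.save(mp)
                    subj.image_path = str(ip)
            subjects.append(subj)
            sid += 1
    if out_path is not None:
        write_cohort_csv(subjects, out_path / "cohort.csv")
    return subjects


COHORT_COLUMNS = (
    "subject_id",
    "label",
    "matched_set_id",
    "age",
    "bmi",
    "parity_class",
    "family_history",
    "age_ftp",
    "hrt_ever",
    "pmd_true",
    "image_path",
)


def write_cohort_csv(subjects, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for s in subjects:
            writer.writerow([getattr(s, c) for c in COHORT_COLUMNS])


def cohort_frame(subjects) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame({c: [getattr(s, c) for s in subjects] for c in COHORT_COLUMNS})
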