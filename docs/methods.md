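# Methods

This note defines every computed quantity in `mammotex` precisely enough to
reimplement it, states the numerical conventions, describes the synthetic
cohort generator and its scope, and lists known limitations.

## 1. Breast delineation (`mammotex.segmentation`)

Input: an 8-bit grayscale image. Four deterministic steps:

1. **Border-stripe removal.** Any row or column within the outer 5% margin of
   the image whose fraction of near-white pixels (gray ≥ 250) exceeds 0.8 is
   set to 0. This removes scanner-edge artifacts without touching interior
   content.
2. **Otsu threshold.** The threshold `t` minimizing the within-class gray
   variance over all 256 candidate values is found from the histogram
   (cumulative-sum formulation; exhaustively equivalent to scanning all
   thresholds). Pixels with gray > t form the foreground. A constant image
   raises `DegenerateHistogramError`.
3. **Morphological opening** with a disk of radius 5 px removes thin bridges
   and small debris (e.g. film labels connected by noise).
4. **Largest 8-connected component** is retained as the breast mask. A result
   smaller than 1% of the image area triggers a warning.

Masks carry a `provenance` flag (`automatic` or `corrected`) so manually
edited masks can be represented.

## 2. Feature bank (`mammotex.features` + `mammotex.texture`)

The catalog is a fixed, deterministic enumeration of 470 features —
76 moment, 86 form, 130 statistical, 108 structural, 70 spectral — in the
order: group (moment, form, statistical, structural, spectral), family,
scale (full, 0.5 cm, 1.0 cm), formula. Feature ids are strings such as
`stat.glcm.contrast@0.5cm`.

### Scales

Only the co-occurrence, sum/difference-histogram, statistical-geometrical and
run-length families are multiscale. Coarse versions use non-overlapping
square blocks of 0.5 cm or 1.0 cm side (the block size must be an integer
number of pixels): a block enters the coarse mask when ≥ 50% of its pixels
are inside the breast; its value is the mean gray of the in-mask pixels,
re-quantized to 16 levels by `mean // 16`.

### Gray quantization

All second-order families operate on 16 gray categories, `level = gray // 16`.
Pixel pairs are taken at unit displacement in the four directions 0°, 45°,
90°, 135°, both orderings, with both endpoints inside the mask, pooled into a
single matrix (rotation-robust pooling).

### Families

- **Gray histogram (16):** relative frequency of each category.
- **GLCM / Haralick (13 × 3 scales):** ASM, contrast, correlation, variance,
  inverse difference moment, sum average, sum variance, sum entropy, entropy,
  difference variance, difference entropy, and the two information measures
  of correlation. Conventions: logarithms base 2 with 0·log 0 = 0; sum
  variance is taken about the sum mean; difference statistics use the
  absolute-difference histogram; a degenerate single-row matrix returns
  correlation 0 with a warning.
- **SDH / Unser (25 × 3 scales):** mean, variance, skewness, kurtosis,
  energy and entropy of the sum histogram (s = i + j ∈ 0..30) and of the
  signed difference histogram (d = i − j ∈ −15..15), plus 13 estimates of
  the Haralick features from the histograms alone. Contrast, correlation,
  variance, IDM and the sum/difference statistics have exact closed forms
  under symmetric accumulation (in particular SDH contrast ≡ GLCM contrast);
  ASM and entropy use the independence approximation; the information
  measures are evaluated on the product-form joint estimate Ps(i+j)·Pd(i−j),
  renormalized.
- **Moments (76):** 4 population central moments of the masked gray values
  (non-excess kurtosis; skewness = kurtosis = 0 for constant regions);
  16 normalized central moments η_pq, p,q ∈ {0..3}, of the intensity-weighted
  spatial distribution about its centroid (η00 = 1, η10 = η01 = 0 snapped
  exactly; the constants are removed downstream by zero-variance
  preselection); Hu's 7 invariants; 49 Zernike magnitudes |A_nm| for
  n = 0..12, n − m even, on the disk circumscribing the mask bounding box,
  centered at the intensity centroid, with pixel-area scaling 1/radius².
- **Form (86):** computed on the binary mask only. Shape scalars: area
  (cm²), perimeter (chain-code length of the Moore-traced boundary, cm),
  compactness P²/4πA, rectangularity (bounding-box fill), circularity
  4A/πd²_max. Normalized radial length (boundary distance to centroid /
  max): mean, SD, 16-bin entropy, fraction above the mean, zero crossings,
  mean absolute successive difference. Fourier descriptors: the boundary
  resampled to 128 equidistant points is a complex sequence; after dropping
  c₀ and normalizing by max(|c₊₁|, |c₋₁|) (robust to traversal direction),
  the summed normalized energies for |k| ∈ 2–5, 6–16, 17–64. Plus the 72
  moment features (NCM, Hu, Zernike) of the mask as a 0/1 image.
- **Structural (108):** Chen's statistical-geometrical features — for each
  threshold α = 1..15 the 16-level ROI is binarized; the number of connected
  regions and the area-weighted mean irregularity
  ((1 + √π·d_max)/√A − 1) of foreground and background form four curves,
  each summarized by max, average, curve-weighted mean and SD (16 features
  × 3 scales). Galloway run-length statistics — short-run emphasis, long-run
  emphasis, gray-level nonuniformity, run-length nonuniformity, run
  percentage — for the four principal directions (20 × 3 scales); runs are
  maximal constant-level segments confined to the mask.
- **Spectral (70):** the mask bounding-box crop, off-mask pixels replaced by
  the mean interior gray, is decomposed by a 3-level 2-D wavelet pyramid
  (periodized boundaries) for the bases haar, db2, db4, coif1, sym2, sym4,
  bior2.2; each of the 10 subbands contributes its mean squared coefficient.
  Subbands are named by the orientation of the spatial frequency they
  capture (`h` = horizontal frequency, i.e. variation along rows' direction
  produced by vertical structures).

## 3. Risk pipeline (`mammotex.risk`)

Public surface in the statsmodels style: `TextureRiskModel(feature_table,
cohort, config).fit()` returns a `TextureRiskResults` with `summary()`.

1. **Split.** Matched sets are randomized 50/50 into training and validation;
   sets stay intact; an odd set count puts the extra set in training.
2. **Preselection.** On training data, zero-variance columns are dropped and,
   greedily in catalog order, any feature with |Spearman ρ| > 0.98 to an
   already-retained feature is removed.
3. **Bootstrap-stability selection** (Sauerbrei–Schumacher). For each of B
   bootstrap resamples of the training half (B = 500 reference, smaller in
   simulations), a backward stepwise logistic elimination under AIC starts
   from all candidate features; the inclusion frequency of each feature is
   the fraction of resamples whose final model retains it. Features with
   frequency > 0.70 are kept; among kept pairs with |ρ| > 0.90 the
   lower-frequency member is dropped (ties: earlier catalog ordinal). This
   runs first within each feature group, then once more across groups
   starting from the union of within-group selections.
4. **Scoring.** A logistic model on the final features (standardized to
   training mean/SD) yields `score = 100·expit(linear predictor)`.
5. **Evaluation.** Validation AUC is the Mann–Whitney concordance of case vs
   control scores. The odds ratio per SD of the score comes from a
   statsmodels logistic fit with Wald 95% CIs, unadjusted and adjusted for
   (age, BMI), the full covariate set (+ parity as two indicator levels,
   family history, age at first-term pregnancy), and the full set + PMD.

### Logistic core

In-package damped Newton/IRLS with a vanishing ridge (1e-8) for collinear
resamples; convergence is declared when the Newton decrement (the expected
log-likelihood gain of the next step) falls below tolerance. Non-convergent
or runaway fits (|β| > 50, a symptom of separation) are flagged; resamples
whose full starting model fails are skipped, and > 10% failures abort
selection. Agreement with `statsmodels.Logit` (coefficients, log-likelihood,
AIC, standard errors) is enforced by tests.

The backward scan has two modes. `"exact"` refits every single-removal
candidate at each step. `"wald"` (default) ranks candidates by their Wald z²
from the current fit — the expected AIC change of dropping x_j is ≈ 2 − z_j²
— and verifies the exact AIC of the leading candidates, probing a few more
before stopping; every accepted elimination is backed by an exact refit, so
the AIC path is monotone under either mode. The two modes agree on every
tested problem; `"wald"` is orders of magnitude faster at bootstrap scale.

## 4. Synthetic cohort generator (`mammotex.synthetic`)

The generator emulates the statistical structure the analysis assumes, not
mammographic anatomy, and is the package's only data source.

- **Covariates.** 2:1 age-matched case–control design. Per-arm
  distributions: age (case 57.5 ± 10.8, control 57.3 ± 10.6, truncated to
  the screening range 25–90), BMI (26.1 ± 5.0 / 24.6 ± 3.8), parity class
  0 / 1–2 / ≥3 (15.5/62.7/21.8% vs 14.3/53.4/32.3%), family history
  (14.4% / 19.7%), age at first-term pregnancy (25.2 ± 4.6 / 25.6 ± 4.4),
  ever-use of hormone replacement therapy (29.8% / 57.5%). Matched triplets
  are built constructively: each control's age fixes a 10-year decade and
  the two case ages are drawn from the case distribution truncated to that
  decade (rejection sampling; an unpopulatable decade raises
  `MatchingError`).
- **Images.** A half-elliptical breast attached to the left edge with
  harmonic boundary wobble; a smooth "fatty" interior field (Gaussian-
  filtered noise, SD 15 gray levels around a mean of 110) whose correlation
  length is a per-subject parameter; soft-edged dense-tissue blobs added
  until a per-subject area-fraction target drawn from (0.05, 0.40) is
  reached, with edge contrast as a second per-subject parameter; optional
  near-white scanner stripes and a film-label blob; dark background (~4).
  Ground truth (breast mask, dense mask, achieved dense fraction) is
  returned alongside.
- **Planted effect.** `texture_effect = δ` shifts the case-arm means of the
  two texture parameters — blob edge contrast (35 ± 5 gray levels) and
  fatty-field correlation length (0.08 ± 0.016 cm) — by δ between-subject
  SDs, leaving covariates and the dense-fraction distribution untouched.
  δ = 0 is an exact null for the texture signal.
- **Reproducibility.** One `SeedSequence` spawns independent substreams for
  covariates, texture parameters and per-image noise, so cohorts are
  deterministic given the config.

## 5. Numerical choices

- Entropies use log₂ with 0·log 0 = 0.
- Population (biased) moment estimators throughout; kurtosis is non-excess;
  zero-variance distributions report skewness = kurtosis = 0.
- Spearman correlations use average ranks for ties.
- Chain-code perimeter: unit steps count 1, diagonal steps √2.
- Zernike radial polynomials are evaluated from precomputed coefficient
  tables shared across all pixels (vectorized Vandermonde formulation).
- AIC = 2(p+1) − 2 log L, counting the intercept.
- AUC ties count one half (Mann–Whitney convention).

## 6. Limitations

- The synthetic generator is a surrogate: its images reproduce the
  *statistical* properties the pipeline consumes (bimodal gray histogram,
  controllable second-order texture, realistic covariate structure) but not
  mammographic anatomy; absolute feature values on real mammograms will
  differ.
- Validation metrics under selection: the odds ratio per SD on the
  validation half is unbiased with respect to feature selection (done on
  training only), but adjusted-model AUCs are in-sample for the adjustment
  covariates.
- The Wald-screened backward scan is an accelerated variant of exhaustive
  backward elimination; although every accepted step is exact-AIC-verified
  and the two modes agree on all tested problems, near-ties can in principle
  resolve differently.
- The manual mask-correction workflow used with real mammograms is out of
  scope; masks here are either automatic or supplied by the caller.
- Bootstrap inclusion frequencies with B = 50 (simulation default) carry
  Monte-Carlo noise of ± ~0.07; the reference protocol uses B = 500.
- Recovery of a planted texture effect in small simulations is limited by two
  noise sources. Feature-estimation noise grows as the texture correlation
  length approaches the pixel pitch and the breast shrinks to a few thousand
  pixels; sampling the finest texture scale with ≥ 2.5 px measurably improves
  recovery. Beyond that, selection and coefficient noise dominate: with B = 50
  bootstraps, ~300 training subjects and an unpenalized logistic score on the
  final features, the validation AUC of a planted 1-SD two-parameter effect
  sits ~0.10 below its ideal value of 0.84, and the final score can
  underperform the best single feature on unlucky splits.
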