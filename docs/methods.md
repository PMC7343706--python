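# Methods

`octplaq` characterizes atherosclerotic plaque tissue in intravascular
optical coherence tomography (OCT) pixel by pixel.  This note records the
models the package implements, the defaults and why they were chosen, what
the built-in phantom does and does not emulate, and the numerical choices a
maintainer would want written down.

## Signal model and attenuation inversion

A polar B-scan stacks A-lines (rows, one per beam angle over 360°) against
depth samples (columns).  The detected intensity along one A-line is
modelled with a single-scattering Lambert–Beer form,

    I(r) = I0 · T(r) · s(r) · exp(−μt r),

where `r` is depth into tissue (mm), `μt` (mm⁻¹) the total attenuation
coefficient (scattering-dominated; absorption is negligible at OCT
wavelengths), and `I0` a backscatter-dependent scale.  Two instrument terms
modulate the signal with *physical* depth from the catheter:

* confocal PSF `T(r) = [((r − z0)/zR)² + 1]^(−1/2)` — beam waist `z0`,
  Rayleigh length `zR`;
* roll-off `s(r) = exp[−((r − zC)/zW)²]` — scan centre `zC`, half width
  `zW`.

Dividing out `T` and `s` and taking logs linearizes the model; `(μt,
log I0)` follow from ordinary least squares of the corrected log signal on
depth.  One convention is used on both sides of the package: the log-slope
is `−μt` (single-pass), and the depth variable in the *fit* is measured
from the tissue entry point of each ray, so intercepts are anchored at the
lumen rather than the catheter.  The simulator uses the identical
convention, which is what makes exact noiseless round-trip recovery a
meaningful oracle (it is asserted to 1e-9 relative error in the tests).

Per-pixel maps are produced by sliding a fit window (default **0.25 mm**,
stride 1 px) over the analysis band `[boundary, boundary + 1.0 mm)` of each
A-line; each pixel takes the fit of the window centred on it, and pixels
within half a window of a band edge take the nearest window that still fits
in the band.  The 1.0 mm band reflects how superficial plaque morphology is
annotated on OCT; the window length is a compromise between slope variance
(shorter → noisier) and spatial resolution of the μt map.  Non-positive
pixels, and pixels at or below the noise floor, are masked out of fits;
the pipeline estimates the floor as the 99th percentile of the
pre-boundary (lumen) intensities, a threshold that bounds the floor from
above — without it, a boundary estimate one pixel inside the lumen leaks a
floor-level pixel into every boundary-anchored window and biases μt low.
Windows with fewer than 3 valid points yield no fit, and A-lines with no
valid window at all (e.g. behind the guide-wire shadow) drop out of the
ROI.

The backscattering coefficient `μb = I0 / I′` is computed only when the
caller supplies the locally available intensity `I′`; it is not estimable
from a single A-line, so the feature stack uses `(μt, log I0)` as the two
optical features, `log I0` acting as the backscatter proxy.

## Lumen segmentation

The lumen boundary is the dark→bright transition along each A-line.  Cost
is the negated forward axial gradient of a 3×3 median-filtered image
(median filtering suppresses speckle before differentiation; filtering and
gradient are scale-covariant, so the segmentation is invariant to global
intensity rescaling).  Dynamic programming minimizes the total cost under a
smoothness constraint |Δr| ≤ s per A-line step (default **s = 2 px**),
including the wrap-around pair.  Circular closure is handled by solving the
DP once per candidate start column — the best column in each of 8 depth
bands by column cost, or every column on narrow rasters, in which case the
search is exhaustive — keeping the cheapest closed path; ties prefer
smaller radii.  On tiny instances the result is asserted equal to full path
enumeration.

Guide-wire shadow detection scores each A-line by its mean intensity and
flags the longest contiguous circular run falling more than `k = 3`
median-absolute-deviations below the across-A-line median (minimum run
3 A-lines).  Shadowed A-lines are excluded from the DP and given circularly
interpolated radii; after integer rounding the interpolated values can
exceed the smoothness bound by 1 px at a gap edge, which downstream code
does not rely on.

## Texture features

All 25 features are computed per pixel from the window centred on it
(default **11×11 px**; clipped at depth edges, continued across the angular
seam, which is periodic).  GLCM, NGTDM and FD operate on the image
quantized to **32 levels** anchored at the global min–max — this populates
small-window co-occurrence matrices and makes those features invariant to
constant intensity offsets.

* **FOS** — population mean, variance, median, skewness, kurtosis
  (standardized 3rd/4th central moments; both defined as 0 for a constant
  window).
* **GLCM** — symmetric, normalized co-occurrence matrices at distance 1
  for 0°/45°/90°/135°; correlation, contrast, dissimilarity, energy
  (angular second moment), entropy (bits, 0·log 0 := 0), homogeneity,
  maximum probability, averaged over the four directions (averaging rather
  than concatenation keeps the feature count at 7).  Correlation of a
  degenerate (zero-variance) matrix is defined as 1.
* **NGTDM** — Amadasun–King busyness, contrast, complexity, coarseness,
  strength for 3×3 neighbourhoods (centre excluded from the neighbour
  mean), with ε = 1e-12 guarding zero denominators; a constant window
  yields coarseness 1/ε and zeros elsewhere.  "Texture length" in the
  historical five-feature naming is the Amadasun *strength*.
* **FD** — differential box counting at scales 2, 3, 4, 5: at scale `s`
  the window is tiled with s×s cells, each contributing
  `ceil(max/h) − ceil(min/h) + 1` boxes of height `h = s·G/M` (G = gray
  range, M = window side; flat cells contribute 1 box).  The four emitted
  features are the per-scale log box counts; their least-squares slope
  against `log(1/s)` is the fractal-dimension estimate and equals exactly
  2 on a flat surface.  Near the deep edge of the raster a clipped window
  falls back to the widest scales it can hold.
* **RP** — x = depth in pixels from the lumen boundary (0 on the
  boundary), y = raw A-line index.  Boundary-relative depth makes the
  position features follow the vessel geometry instead of the catheter.

## Classifier

A random forest (scikit-learn) with **Ntree = 100** trees and **Mtry = 5**
features per split (⌊√25⌋; ablation sets with fewer features use ⌊√p⌋).
Calcified pixels are typically the rarest class, so balanced class
weighting is the default.  Prediction is the per-pixel argmax of ensemble
votes with ties resolved toward the lower class index (fibrous < calcified
< lipid); non-ROI pixels are background, and per-class probability rasters
sum to 1 on the ROI.  Training is deterministic given the seed, and
prediction is invariant to feature-stack row order.

## Evaluation

Pixel-wise one-vs-rest sensitivity and specificity are computed on
annotated pixels only (truth labels 1–3; predicting background on an
annotated pixel is a miss).  Two per-class "accuracy" flavours are emitted
and labelled: per-class recall averaged per image (the quantity summarized
by the cross-validation tables) and standard one-vs-rest binary accuracy.
Prevalence-weighted per-class sensitivities reproduce overall accuracy
exactly, which the tests assert.

Cross-validation partitions whole images into k groups (default 10 folds
of 5 images — images are never split), trains per fold on the remaining
images, and reports mean ± SD and median per class for each feature-set
ablation (OP+RP, FOS+RP, GLCM+RP, NGTDM+RP, FD+RP, ALL).  A patient-level
holdout split (whole patients held out) is provided separately.

Annotation agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measurement — with the F-based 95% CI (pingouin),
Bland–Altman bias with limits of agreement `bias ± 1.96·SD(diff)`, and OLS
of rater 2 on rater 1.

## The phantom: what it emulates, what it does not

The forward-model simulator renders annular three-tissue geometries around
a smooth lumen (mean radius plus low-order harmonics), with per-tissue
`(μt, I0)` driving the same signal model the fitter inverts, cumulative
attenuation across tissue transitions, confocal/roll-off modulation, and:

* fully developed speckle — multiplicative unit-mean gamma noise with
  **L = 4** looks (frame-averaged speckle; `L=None` is the noiseless
  limit);
* per-tissue multiplicative texture `1 + amp·(smoothed unit-variance
  noise)` with tissue-specific amplitude and correlation length;
* a bright 2-px ring on calcified borders, mimicking the sharply
  delineated calcification edges seen on OCT;
* a guide-wire shadow sector collapsing to the noise floor beyond the
  lumen;
* 16-bit integer quantization matching the on-disk representation.

Default tissue parameterisation: fibrous μt 2.0 mm⁻¹, bright and
homogeneous; calcified μt 3.2 mm⁻¹, weakly backscattering, texturally busy
with border rings; lipid μt 6.5 mm⁻¹, bright superficially with fast
decay.  These place fibrous/calcified close in attenuation (so optics
alone confuses them) and make calcified distinctive mainly through
texture, which is what gives the combined feature set its edge in the
end-to-end check.

The study suite groups frames into synthetic "patients" sharing base lumen
geometry and sector layout with frame-to-frame jitter.  Deliberately *not*
simulated: blood/saline artifacts, catheter sheath reflections, NURD
distortion, side branches, intra-tissue heterogeneity beyond the texture
field, and the OCT→histology co-registration error that dominates real
annotation noise.  Passing the end-to-end check therefore shows the
pipeline recovers what the forward model encodes — it does not certify
clinical performance on real pullbacks, where class overlap is far larger.

## Problem sizes and runtime

Simulated frames are 96 A-lines × 220 depth px at 10 µm axial spacing
(a reduced grid relative to a C7-XR frame; the geometry is configurable
through `SystemParams`), and the study cross-validation subsamples 600 ROI
pixels per image, which keeps the 50-image, 6-ablation, 10-fold experiment
in the minutes range while leaving thousands of test pixels per fold.
Monte-Carlo checks use 1,000 replicate A-lines (attenuation bias), 100
random patches (texture oracles), and 10,000 pairs (Bland–Altman).

## Known limitations

* The per-class "accuracy" of the original table layout this mirrors is
  not a standard quantity; both interpretations are emitted (see above).
* `μb` requires a user-supplied `I′`; there is no in-package estimator.
* The DP closure search is exact only when every column is a start
  candidate (always true for ≤ 8-column rasters and in the tests); with
  the default 8 candidate buckets it is a very good heuristic, not a
  proof.
* Attenuation fits assume single scattering; depth-resolved
  (Vermeer-style) or multiple-scattering models are out of scope.
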