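# Methods

`gfptract` quantifies how much of an insect female's sperm-storage
organs are occupied by GFP-tagged sperm, and tests how male heat
stress, prior female mating, and time since insemination change that
occupancy. It has three layers: a ground-truthed synthetic micrograph
and experiment generator, an image-quantification chain, and an
overdispersed-GLM inference stage. This note documents the models, the
defaults and why, and what the synthetic results do and do not show.

## Imaging model

A sample is a 14-bit two-channel micrograph (plus bright-field) of a
stylized reproductive tract:

    green = I(x, y) * (P(x, y) + k * R(x, y)) + noise
    red   = I(x, y) * R(x, y) + noise

- `P` — sperm-head fluorescence: `n_puncta` spots placed uniformly in
  the tract polygon (plus optionally extra spots confined to the
  spermatheca). Each spot is a truncated super-Gaussian
  `A exp(-(d^2/2 sigma^2)^m)` with amplitude `A ~ U(3000, 6000)`,
  width `sigma = 2 px`, order `m = 8`, cut to exactly zero beyond
  `4 sigma`. Overlapping spots combine by per-pixel maximum, emulating
  occlusion/saturation of stacked heads in projection. Flat-topped
  spots matter twice: they give the corrected-image histogram a genuine
  second mode (a prerequisite for intermodes thresholding), and they
  make the above-threshold area insensitive to exactly where between
  the modes the threshold lands. With soft Gaussian spots the histogram
  is monotone and a midpoint threshold would undercount cover roughly
  threefold. A spot's *footprint* — the ground-truth sperm mask — is
  the set of pixels above 10% of its peak.
- `R` — autofluorescent material: sharp chitin polygons (a "chitin
  ring" near the spermathecal duct, amplitude 3000, and an
  ovipositor-like wedge, 2500; edges softened by a 1 px Gaussian) plus
  a smooth diffuse tissue glow (level 150, 8 px blur) over the tract.
  The green channel sees `k` times this red structure; `k = 0.3` by
  default and is the ground truth for the correction factor.
- `I` — smooth uneven illumination, a low-order 2-D polynomial on
  [-1, 1]^2 (default coefficients give a few-percent tilt and sag).
- noise — Poisson shot noise at detector gain 1.0 intensity unit per
  photon plus Gaussian read noise (s.d. 10), then clipping to
  [0, 16383] and rounding to the integer grid of acquired data. With
  gain and read noise set to 0 the generator returns exact float
  intensities (an idealized-optics diagnostic mode).

Amplitude and background levels are package choices on the 14-bit
scale (real intensities in such assays span roughly 6 to 11000); no
published values exist for them. Gain 1.0 was fixed during one-time
calibration: the correction step clips negatives to zero, so noise
rectification leaves a small positive residual in autofluorescent
regions, and the residual stays below 2% of the uncorrected signal
only when shot noise is modest relative to the chitin signal.

Three labelled polygon ROIs accompany each scene: `total_tract`,
`spermatheca`, and an `autofluorescence_reference` placed inside the
chitin ring. Sperm avoid the reference structure (that is what makes it
usable as a sperm-free reference), so spot placement keeps a clearance
of `4 sigma + 1 px` around it when space allows; the reference ROI is
then jittered inside the ring until no spot's rendered support can
touch it, and the generator raises after 60 failed attempts.

## Quantification chain

Fixed order, per sample:

1. **Rolling-ball background subtraction**, radius 25 px, each channel.
   Implemented as the classical grayscale opening with the ball height
   profile (erosion then dilation, image-domain restricted); negatives
   clip to zero, so output never exceeds input. No downsampling
   heuristics. Note the opening exhibits an intrinsic "ball sag" within
   one radius of the image border under tilted backgrounds; interior
   pixels are exact.
2. **Correction factor**: `Int_GFP / Int_Auto`, the mean
   background-subtracted green and red intensities over the rasterized
   reference ROI (error if the red mean is below 1e-6). One factor per
   sample, applied to both site ROIs.
3. **Crosstalk correction**: `max(green - factor * red, 0)` pixelwise.
4. **Intermodes threshold** per site ROI: 256-bin histogram over the
   full 14-bit range, smoothed with a 3-point moving mean until exactly
   two local maxima remain (plateau-aware; cap 10 000 iterations);
   threshold = midpoint of the two mode-bin centres. A histogram that
   is or becomes unimodal raises; the configured fallback treats the
   ROI as blank (cover 0, no presence) and flags it — in this context a
   unimodal histogram is an empty tract.
5. **Occupancy metrics**: mean and median (mean-of-central-pair) over
   all ROI pixels of the corrected image; percentage cover = pixels
   strictly above threshold / ROI area x 100; presence = at least one
   8-connected above-threshold component of >= 4 pixels (configurable).

ROI rasterization uses the pixel-centre even-odd rule in 0-based
coordinates (a pixel belongs to the polygon iff its centre
`(x + 0.5, y + 0.5)` is inside), which makes area counts exactly
reproducible. Polygons must be simple (validated), so the even-odd and
winding rules coincide.

Mean intensity is computed over all ROI pixels, not only
above-threshold ones, consistent with measuring the corrected image
within the ROI boundary. Intensities are never compared across the two
sites, which represent different acquisition contexts (exposure sets).

## Experiment generator

The factorial design is 2 (male thermal treatment: control / heat) x 2
(female status: virgin / previously mated) x 2 (time: 30 min / 24 h)
with default cell sizes (23, 25, 24, 25, 22, 24, 23, 24) in
time-outermost, status, thermal-innermost order — 190 females, two
site records each. Factor effects are multiplicative on the response
scale. Defaults encode the study-scale conditions: on cover, heat
multiplies the tract by 0.68 and the spermatheca by 0.66, storage time
multiplies the tract by 0.28 (spermatheca 1.0), and a prior competitor
multiplies the spermatheca by 0.30 (tract 1.0); on intensity the
corresponding multipliers are 0.79/0.64, 0.35/1.0 and 0.42/1.0.

- **Cover** is drawn beta-binomially with denominator 100 around the
  cell's expected proportion (baselines 40% tract, 35% spermatheca);
  the intraclass correlation `rho = 0.05` yields a quasi-binomial
  dispersion of about `1 + 99 rho ~ 6`. Beta-binomial is the standard
  generative counterpart of quasi-binomial fitting and keeps cell means
  exactly equal to the injected proportions.
- **Intensity** is Gaussian truncated at zero around the cell mean
  (baselines 3000 / 2500; s.d. 500). The s.d. keeps truncation
  negligible even in the smallest default cell (mean ~830), so the
  ratio of cell means equals the injected multiplier to well under 2%.
- **Paternity**: brood size ~ Poisson(30); the focal male's offspring
  count is beta-binomial (`rho = 0.10`) with arm proportion 0.60
  (control) shifted by -1.66 log-odds under heat — a 63% lower P2.

Because multiplicative effects on an identity (Gaussian) or logit
scale are not additive, simultaneous strong effects genuinely induce
link-scale interactions; the reduction step may legitimately retain
them on intensity responses. Calibration and recovery checks therefore
inject single factors (the truth is then one well-specified
coefficient); this is a property of the model family, not a defect of
the fitter.

The full image-based pipeline maps cell effects into scenes: expected
cover determines a Poisson punctum count through the uniform-placement
coverage formula `cover = 1 - (1 - a/A)^N`, intensity multipliers scale
spot amplitudes, and a shared lognormal per-female factor (s.d. 0.25)
supplies the between-female overdispersion the downstream
quasi-binomial model expects.

## Inference

- Percentage cover enters a logit-linked quasi-binomial GLM as the
  pair (percent, 100 - percent); non-integer values are permitted
  (quasi-likelihood needs no integers). Mean intensity enters an
  identity-linked Gaussian GLM, fitted as OLS (to which Gaussian IRLS
  reduces exactly). Reference levels are control / virgin / 30 min.
- Dispersion `phi` = Pearson chi-squared / residual df, estimated on
  the fitted model; it rescales standard errors only — coefficients are
  dispersion-invariant by construction.
- drop1 LLRTs: for continuous responses
  `F = (dDeviance / ddf) / phi` against F(ddf, df_resid); for bounded
  proportions the scaled deviance `dDeviance / phi` against
  chi-squared(ddf). The scaled variant is essential under
  overdispersion — without it the nominal 5% test rejects far too
  often.
- Model reduction starts from all three mains plus all two-way
  interactions (no three-way term), repeatedly dropping the least
  significant interaction with p >= 0.05 and refitting; mains are never
  dropped. A main effect blocked by a retained interaction is reported
  through a type-II-style LLRT (tested in the model stripped of
  interactions containing it), so the summary table always carries all
  three design factors.
- Post-hoc contrasts are Wald statistics coefficient / SE (z for
  quasi-binomial, t for Gaussian) straight from the fitted model.
  Percent changes are reported twice: model-adjusted (response-scale
  predictions with non-focal factors balanced equally across levels)
  and raw group-mean ratios, since the two need not agree.
- Pseudo-R^2 = 1 - residual deviance / null deviance (reported as NaN
  for a degenerate constant response). AIC is not used for model
  comparison: it is undefined under quasi-likelihood, so comparison
  rests on LLRTs alone.
- Residual df is reported as n - p (186 for 190 observations, three
  two-level factors and intercept).
- **No multiple-testing correction is applied anywhere.**
- Spearman correlations among metrics use average ranks for ties and
  report both rho and S = sum of squared rank differences.

## Numerical choices and degenerate inputs

- Histogram bimodality counts plateau runs as single maxima; twin
  delta histograms resolve immediately to the exact midpoint.
- Deviances below 1e-10 of the null deviance are treated as exactly
  zero, so perfect fits yield statistic 0 / p = 1 rather than ratios of
  float residue.
- A term contributing no columns (single-level factor) or leaving df
  unchanged raises, as do aliased designs (rank check), separation
  (non-finite coefficients), zero-variance inputs to Spearman, and
  empty ROI masks.
- Groups of size one report s.e. 0 with n = 1 left visible as a flag.

## What passing tests show — and what they do not

The generator reproduces the statistical structure the analysis
assumes: punctate signal over structured autofluorescent background
with known crosstalk, and overdispersed factorial responses with known
multiplicative effects. It does not model sperm physiology (motility,
viability, displacement mechanics), optical blur beyond the spot
profile, chromatic aberration, tissue deformation between channels, or
operator variability in ROI tracing. Passing tests therefore certify
the measurement and inference machinery — thresholds recover injected
cover to within ~2 percentage points, the correction factor to within
5%, effects and their uncertainties to nominal coverage — not the
biological conclusions drawn from any real dataset. Real-data use goes
through `run_quantify` on TIFF/ROI directories and `run_analyze` on
the resulting per-female table.

## Problem sizes

Default scenes are 128 x 128 px, which keeps the ball-opening radius
(25 px) meaningful while a 190-female image-based run, quantification
and inference included, completes in about a minute. Calibration
checks use 500-2000 simulated experiments at the published design
sizes; imaging properties use 50-200 seeded scenes.
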