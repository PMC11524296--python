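# Methods

`firspec` implements a complete near-infrared hyperspectral chemometrics
workflow for estimating two physiological traits of conifer seedlings —
needle leaf chlorophyll content (LCC, mg per g fresh weight) and needle leaf
water content (LWC, water fraction of fresh weight) — from canopy reflectance
spectra on a 512-band grid spanning 870–1720 nm. Because the original
seedling dataset is not publicly deposited, the package ships a first-class
synthetic-data generator that reproduces the statistical structure of that
study design, and every pipeline stage is developed and tested against it.

## The imaging model

A push-broom NIR imager produces a raw intensity cube I (lines × samples ×
bands). Reflectance is recovered by white/dark normalisation

    R = (I − D) / (W − D)

where W is a white-panel reference and D the dark-current reference.
References may be full frames (per-pixel, per-band) or scan-line frames
(samples × bands) broadcast along the scan axis; both dialects occur in
practice and both are supported. Calibration refuses to divide where W = D
and names the first offending (line, sample, band).

The canopy region of interest is a brightness mask: a pixel is kept when its
mean reflectance across bands is at least 0.45 (boundary inclusive — the
threshold reads as an attained lower bound). The statistic is configurable to
a single named band; whether the original workflow used a band statistic or a
single band is not documented, so neither is asserted. No morphological
cleanup is applied by default. The per-seedling spectrum is the arithmetic
mean over masked pixels.

Cubes are stored in the ENVI convention (text header + raw binary, BSQ and
BIL interleaves); the round trip is bit-lossless.

## Wet-lab reference traits

Chlorophyll from ethanol-extract absorbance:
Ca = 13.95·D665 − 6.88·D649, Cb = 24.96·D649 − 7.32·D665, CT = Ca + Cb
(mg/L), and LCC = CT · (VT/1000) · BT / W in mg/g with VT the extract volume
in mL, BT the dilution ratio and W the fresh weight in g. The division by
1000 bridges mg/L × mL → mg; the formula as usually printed leaves the unit
conversion implicit, so it is stated here explicitly. Negative concentrations
are flagged (`suspect`), never clamped, so bad plate readings surface in QC.
Absorbance at 470 nm is read alongside but feeds no formula; it is carried
through untouched. Water content is gravimetric: LWC = (M1 − M2)/M1,
a fraction internally; percent is a formatting concern.

## The synthetic generator

The generator emulates the drought-gradient study conditions: 180 seedlings,
five groups of 36 (D0, D14, D28, D42, D56 — days of osmotic drought), group
mean LCC declining 2.4 → 1.8 → 1.2 → 0.6 → 0.1 mg/g and LWC 0.68 → 0.55 →
0.40 → 0.25 → 0.09. The endpoint means are the study's reported group
averages; the intermediate values interpolate the reported monotone decline.
Within-group spread is normal with sd = 10% of the group mean (visible spread
without overlap at the extremes), truncated at physical bounds (LCC ≥ 0,
LWC ∈ [0,1]) by resampling.

A spectrum is generated as

    x(λ) = g · [ b(λ) − Σ_f d_f · exp(−(λ − c_f)² / 2w_f²) ] + o + ε(λ)

* b(λ): gentle quadratic baseline continuum (coefficients 0.85, −0.08, −0.05
  on a centred, span-normalised wavelength coordinate), chosen so SG and MSC
  are exercised by curvature, not just offsets.
* Absorption features: water O–H overtone bands at 970 nm (width 45 nm,
  depth 0.25·LWC) and 1450 nm (60 nm, 0.55·LWC); chlorophyll-linked N–H/C–H
  bands at 1100 nm (35 nm, 0.08·LCC) and 1190 nm (40 nm, 0.06·LCC). Depths
  are linear in the traits, which makes ground truth recoverable by linear
  calibration models and keeps the generative map injective in (LCC, LWC).
* Scatter: per-sample affine distortion, gain ~ N(1, 0.05), offset ~
  N(0, 0.01), plus slope/curvature jitter of the baseline with sd tied to the
  offset sd. Tying the baseline jitter to the scatter scale makes the
  zero-scatter, zero-noise configuration an exactly deterministic function of
  the traits (two samples with equal traits produce identical spectra), which
  several invariants rely on.
* Noise: additive Gaussian, sd 0.002 reflectance units — a typical
  high-signal NIR noise floor. Output clipped to (0, 1.2].

The noise and scatter magnitudes are fixed defaults representing a
well-behaved laboratory acquisition; they are deliberately modest because the
generator's purpose is to verify the machinery, not to stress-test it.

What the generator does **not** emulate: radiative-transfer leaf optics
(PROSPECT-style), illumination geometry, sensor PSF, band-to-band correlated
noise, or nonlinear trait–depth saturation. Passing tests therefore
demonstrate that the pipeline recovers traits when its modelling assumptions
hold; they say nothing about accuracy on real canopies, where the published
numbers came from a dataset that is not publicly available.

The cube generator wraps a sample's clean spectrum into a scene: a centred
canopy disk carrying the spectrum (plus per-pixel noise) over a dark
background (reflectance 0.05), a white frame near full scale (4000 DN) with a
smooth illumination falloff, and a dark frame at the sensor offset (100 DN).
The ground-truth mask is returned so mask recovery is testable; a scene too
small to contain the disk yields an empty mask and exercises the degenerate
path.

## Preprocessing

Three row-wise transforms, compared and composable:

* **SG** — Savitzky–Golay least-squares polynomial convolution. Defaults
  window 11, order 2, derivative 0 (plain smoothing); the derivative is
  exposed as an option. The unstated original settings make these defaults a
  design choice; window 11/order 2 is common NIR practice. Edges use
  polynomial extrapolation on the truncated window (no padding artifacts);
  the derivative step is per band index.
* **SNV** — per-spectrum centering and division by the **population** sd
  (ddof = 0; stated because it fixes the two-band worked example at ±1).
* **MSC** — OLS of each spectrum on a reference (x ≈ a·r + b), corrected
  spectrum (x − b)/a. The reference defaults to the calibration-set mean and
  is frozen in the `Preprocessor` before prediction data is touched; |a| below
  1e−12 is a degeneracy error.

## Wavelength selection

**SPA.** Chains of minimally collinear bands grown by orthogonal projection:
from a start band, repeatedly project unselected columns onto the orthogonal
complement of the selected span and take the largest residual norm (verified
against an explicit-projector oracle). Chains of length `k_max` are grown
from every start band; each prefix is scored by multiple linear regression
RMSE on a seeded 80/20 holdout within the calibration set (the validation
scheme being unstated originally, holdout is the package's choice; a 0
holdout fraction scores in-sample and is fully deterministic). Rank
deficiency truncates a chain with a warning. `k_max` must stay below the
training row count or MLR is underdetermined. The winner is the global RMSE
minimum; ties go to the smaller subset, then the lexicographically smaller
index list.

**CARS.** N = 50 Monte-Carlo runs (80% of calibration rows each). Per run, a
PLS model on the surviving bands ranks bands by |regression coefficient|.
The survivor count follows the exponentially decreasing function with the
boundary conditions of the original CARS formulation — all p bands at run 1,
exactly 2 at run N:

    r_i = a·e^(−k·i),  a = (p/2)^(1/(N−1)),  k = ln(p/2)/(N−1)

(the ceil of r_i·p is taken with a 1e−9 guard so float error cannot push the
boundaries off p and 2). Which bands survive is adaptive reweighted sampling
implemented as weighted sampling **without replacement** with weights
∝ |coefficient|: the common draw-with-replacement-then-deduplicate variant
systematically undershoots the EDF schedule (by tens of percent in early
runs), whereas without-replacement sampling keeps the retained-count sequence
exactly on the schedule while preserving the competitive, stochastic
character. Zero-weight bands are only drawn when fewer competitive bands
remain than the schedule requires. Every run's band set is scored by ten-fold
cross-validated PLS RMSE on the full calibration set; a degenerate run is
skipped with a warning, never silently scored. The run with minimal RMSECV
wins (same tie rule as SPA). The PLS component count inside CARS is either
fixed (`pls_components`) or chosen per run by a small inner 5-fold CV up to
`max_pls_components` (default 10).

## Calibration models

All three families share one fit/predict contract: band identities travel
with the model, prediction inputs are aligned by identity (permutation-safe),
and unknown or missing bands are contract errors. Scaling statistics, MSC
references, selected bands and hyperparameters are always calibration-only
and frozen. A constant training target short-circuits to a constant
predictor.

* **PLSR**: NIPALS partial least squares (scikit-learn backend), centred but
  unscaled bands. Component count fixed or chosen by 10-fold RMSECV up to
  min(20, rank). At full rank it reproduces OLS; with one component on one
  band it is simple linear regression (both are tested limits).
* **SVR**: epsilon-insensitive RBF kernel, grid search (C ∈ 0.1…1000,
  γ ∈ 1e−3…1, ε ∈ {0.01, 0.1}) by 5-fold CV, inputs standardized with
  calibration statistics. Kernel and grid are the package's choice (standard
  chemometrics practice); the originals are unstated.
* **ANN**: one hidden layer (default 10 tanh units), linear output, Adam with
  early stopping on an internal 15% validation split, patience 200 epochs,
  max 3000 epochs, all seeded. The long patience matters: with small
  learning-rate Adam the validation loss can plateau for >50 epochs before
  the network escapes its initial regime, and a short patience stops training
  at a useless model. With identity activation the class collapses to linear
  regression (tested against OLS). Architecture and optimizer settings are
  design choices; the original hyperparameters are unstated.

## Evaluation

Stratified-by-group 70/30 split (exactly 126/54 at n = 180), seeded, with
per-group allocation by largest remainder so each group's proportion is
within one sample of the global fraction. Metrics are

    R² = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ)²,   RMSE = √(Σ(yᵢ−ŷᵢ)²/n)

computed on calibration (subscript C) and prediction (subscript P) sets; R²
is undefined (an error) for a constant reference vector. `run_pipeline`
crosses {none, SG, SNV, MSC} × {full, SPA, CARS} × {PLSR, SVR, ANN} ×
{LCC, LWC} per configuration, confines all fitting to the calibration split,
caches one selection per (preprocessing, selector, target), and emits one row
per cell; a failing cell is marked `failed` with its reason and the run
continues, so comparison tables are always complete.

## Problem sizes and numerical choices

The shipped analyses and the acceptance script use the full default dataset
(180 × 512) with SPA chains up to k = 30 from all 512 start bands and 50-run
CARS; selector-oracle and EDF checks run on small instances (≤ 512 bands,
tens of samples) where brute-force verification is exact. In CARS-over-512
runs the PLS component count is fixed at 8 rather than inner-CV'd, trading a
per-run model-order search for a single representative order; on the
synthetic data the choice is insensitive (the trait signal is low-rank).
Tie-breaks are everywhere deterministic (smaller subset, then lower band
indices), seeds flow from a single integer per entry point, and fixed seeds
give bit-identical outputs end to end.

## Known limitations

* The generator's linear trait-to-depth map makes the calibration problem
  easier than real canopy optics; absolute metric values on synthetic data
  are not comparable to values on real seedlings.
* SPA's exhaustive start-band scan is O(p²·k·n) and is the slowest stage at
  512 bands; it is fine at this scale but would need start-band subsampling
  for much larger grids.
* The published characteristic-wavelength lists are carried as reference
  inputs; data-dependent quantities from the original study (optimal CARS
  run numbers, exact subset sizes) are not asserted as reproducible and are
  not targets.
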