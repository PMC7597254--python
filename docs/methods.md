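# Methods

This note describes the models implemented in `sto2stress`, the
assumptions behind them, the conventions of the synthetic-data
generators, and the limits of what the package's tests establish.

## Spectral model and StO2 estimation

A hyperspectral acquisition is a reflectance cube `R(row, col, λ)` with a
strictly increasing wavelength axis in nanometres.  Optical density is
computed against an explicit white-standard spectrum,

    A(λ) = −log10( R(λ) / R_ref(λ) ).

Base 10 is the optical-density convention; the choice of base is absorbed
into the fitted coefficients and is fixed only for reproducibility.  No
implicit calibration is performed — the reference is always an input.
Pixels with non-positive reflectance (shadow, saturation, dead elements)
are masked and stay masked through every derived product; they are never
zero-filled, because silent zeros would bias region means.

In the 518–580 nm analysis window, the dominant skin chromophores are
oxyhemoglobin, deoxyhemoglobin and melanin.  Per pixel the package fits
the modified Beer–Lambert mixture

    A(λ) ≈ ε_HbO2(λ)·c₁ + ε_Hb(λ)·c₂ + ε_mel(λ)·c₃ + b,

with c₁, c₂, c₃ ≥ 0 (physical non-negativity) and the wavelength-flat
offset `b` unconstrained.  The flat offset absorbs scattering and
baseline losses and is the "modified" element of the model.  Saturation
is the coefficient ratio `StO2 = c₁ / (c₁ + c₂)`, marked invalid when
`c₁ + c₂` falls below a floor (default 1e-6 in basis units) to avoid 0/0
on hemoglobin-free or failed pixels.  The solver is bounded-variable
least squares; a vectorised unconstrained solve handles the
(overwhelmingly common) interior-solution pixels, with a per-pixel
bounded re-solve only where a constraint activates.  The raw saturation
image is then smoothed with a mask-aware square moving average (default
5 × 5; each valid pixel averages only the valid pixels in its window,
renormalised by their count), reflecting that single-pixel StO2 estimates
are influenced by surrounding tissue.

**Extinction basis.**  The packaged basis
(`data/chromophore_basis_synthetic.csv`, also generated analytically by
`sto2.default_basis`) is a smooth synthetic approximation of the
published band shapes — HbO2 beta/alpha bands near 542/577 nm, the single
broad Hb band near 556 nm, melanin as a power-law decay — in arbitrary
consistent units.  It is *not* a literature table: absolute
concentrations are therefore not interpretable, but StO2 is a ratio fitted
against a shared basis and is invariant to any consistent rescaling of
the basis columns (tested).  Any user basis can be supplied as a CSV with
columns `wavelength_nm, eps_hbo2, eps_hb, eps_mel`; it is linearly
resampled onto the cube's in-window grid.

Non-goals of the spectral model: adipose-tissue absorption (negligible
below 700 nm), multi-layer skin models, and spectrally varying
differential pathlength.  Absolute StO2 readings may be offset for a
given person; the downstream features are within-person differences and
cancel any person-fixed offset.

## Registration to the standard face

All maps are compared on a fixed 513 × 911 standard-face canvas with 65
reference key points.  The published standard face (an average of 100
aligned faces) cannot be reconstructed, so the package ships a
*synthetic* parametric 65-point reference layout
(`registration.standard_landmarks`) on the same canvas and accepts any
user-supplied canvas/landmark pair.

The warp is a full fourth-order bivariate polynomial — all 15 monomials
`x^i y^j`, `i + j ≤ 4`, per output coordinate — fitted by least squares
on the 65 correspondences as a *backward* mapping (canvas → source) and
applied with bilinear resampling, which cannot leave holes.  Monomials
are evaluated in coordinates centred on the landmark centroid and scaled
by the half-extent: raw quartic terms over hundreds of pixels produce a
catastrophically ill-conditioned design matrix.  Per-landmark residuals
are kept on the fitted warp; a rank-deficient configuration (e.g.
collinear landmarks) raises a conditioning error rather than returning a
silently unstable fit.  A canvas pixel is valid only when all four source
neighbours are valid and in-bounds, so no valid output ever draws on
invalid input.  No mirror flip is applied anywhere: image-left is the
participant's right side, hence ROI2 = right cheek and ROI4 = left cheek.
Values warped into ear regions do not represent ear tissue (the key
points exclude the ears) and the ROI layout avoids them.

## ROI geometry and delta features

Seven regions on the canvas: ROI1 forehead, ROI2 right cheek, ROI3 nose,
ROI4 left cheek, ROI5 chin, ROI6 philtrum, ROI7 meixin (glabella).  The
exact outlines are not published; the packaged default is a qualitative
rectangle layout stored in fractional canvas coordinates (so it scales
with any configured canvas) and is configuration, not a constant — any
YAML polygon file keyed `ROI1..ROI7` replaces it.  Because a single
shared raster defines each region, ROI areas are identical for every
participant by construction.

A region mean is valid only when at least 50% of the ROI's pixels are
valid (robustness against warp-edge masking).  Quartiles in the boxplot
summary use linear interpolation (the inclusive convention).  The
classification feature is the per-ROI delta mean: ES − ES_baseline
(label ES) and PS1 − PS_baseline (label PS), two rows per participant;
baseline subtraction removes person-level offsets such as adipose or
melanin bias.  The recovery contrasts PS2 − PS1 and PS2 − PS_baseline
satisfy additivity with PS1 − PS_baseline exactly.

## Classification protocol

All 2⁷ − 1 = 127 non-empty ROI subsets are enumerated (by size, then
lexicographically) and each is scored by repeated stratified 5-fold
cross-validation (default 50 repeats; the bundled end-to-end runs use 10
repeats, which keeps the full 127-subset search around two minutes at
identical conclusions).  Within each fold, features are standardised with
training-fold statistics only.  The score is the *classification rate*:
per-class recall pooled over a repeat's folds, averaged over the two
classes and over repeats, in percent.  Stratified folds (rather than
fully random) keep per-fold class ratios balanced, matching the per-class
rate reporting.  Fold assignments are a pure function of the seed, so
every subset and every algorithm under one seed sees identical splits.

The default classifier is an RBF-kernel SVM with C = 1 and
γ = 1/(d·Var) (scikit-learn's `scale`); alternates are linear
discriminant analysis, logistic regression, 5-NN, a decision tree and
bagged trees ("ensemble"), all under the same protocol.  No
multiple-testing correction is applied across the 127 subsets; the
selected subset's rate is a maximum over candidates and is flagged as
selection-biased wherever it is reported.

**Cheek comparison.**  ROI2 vs ROI4 delta features are compared over all
rows, ES rows and PS rows with a two-sample equal-variance t-test
(`h = 1` iff `p < 0.05`, with confidence interval and statistic).  A
paired variant is available and is the *calibrated* choice on this
pipeline's features: the two cheek columns are per-participant pairs and
share each participant's global physical-stress sign, a strong positive
correlation that makes the unpaired test severely conservative on the
pooled and PS contrasts (near-zero type-I error instead of the nominal
5%).  The null-calibration check therefore exercises the paired test,
which rejects at 2–6% across contrasts at α = 0.05.

## Synthetic-data conventions

Generators are pure functions of (config, seed) and store every quantity
they inject.

**Forward cubes.**  `generate_cube` maps a true StO2 image (with
total-hemoglobin, melanin and offset maps) through the same mixture model
in the forward direction, `R = R_ref·10^(−[ε·c + b])`, plus optional
i.i.d. Gaussian reflectance noise.  Inversion on noiseless cubes is exact
to solver precision (< 1e-6 in StO2); at 0.5% reflectance noise the
smoothed map's RMSE is ~0.002 at the default settings.

**Deformations.**  `generate_landmarks` builds a true canvas→source
transform as identity plus a random quartic perturbation with a
prescribed RMS landmark displacement (default 5 px), plus optional
landmark jitter.  The deformed image is the truth map pulled through the
numerically inverted transform (fixed-point iteration; the transform is
near-identity).  Because the truth lies inside the quartic family, the
fitted warp recovers it at the landmarks — the residual then measures
jitter, not model error.

**Cohorts.**  `generate_cohort` emulates the study layout: 42
participants × 5 conditions (ES_baseline, ES, PS_baseline, PS1, PS2) of
registered maps on the standard canvas — 210 maps.  Per participant, a
baseline level (N(0.65, 0.03)) plus a smooth anatomical field (SD 0.02)
is shared by all five conditions, so baseline subtraction removes it;
condition surfaces add the drawn per-ROI deltas on the ROI rasters and a
global term elsewhere; every acquisition gets its own smooth noise field
(SD 0.002) and white pixel noise (SD 0.003), and values are clipped to
[0, 1].  Smooth fields are synthesised on a coarse grid and bilinearly
upsampled, making generation cost independent of correlation length.

Effect structure (defaults, saturation units):

* **ES**: forehead +0.040, right cheek +0.030, left cheek +0.040, meixin
  +0.050; nose ~0; chin and philtrum small mixed-sign — matching the
  qualitative regional trend under emotional stress.
* **PS1**: a participant-global sign, negative with probability
  `p_down = 0.6`; down-participants draw negative magnitudes ~0.030–0.035
  in every region.
* **PS2** = PS1 + `recovery`·(baseline − PS1) with `recovery = 0.5`:
  deltas shrink toward zero but do not vanish, for both directions.

**The planted best subset.**  The spec of the search demands a known
right answer, and a plain Gaussian mean-shift cannot provide one: with a
single displacement vector, a subset of k informative regions separates
classes at ~√k·g, so the margin of a triple over its best pair is only
√3/√2 and is routinely erased by finite-sample (n = 84) spurious
correlations in the remaining regions.  The generator therefore plants
structure: PS-up participants are a balanced three-variant mixture, each
variant reproducing the ES facial pattern except in exactly one of ROI4
(left cheek, displaced to −0.025), ROI5 (chin, to +0.075) or ROI7
(meixin, to −0.025), at ≥ 7 within-class SDs (SD 0.008 in these regions,
0.022 elsewhere).  Any subset missing one of the three regions overlaps
a whole PS-up subpopulation with the ES cluster and caps near 93–98%;
{ROI4, ROI5, ROI7} separates every subpopulation with a large margin and
saturates.  Variants are assigned round-robin among PS-up participants so
no subpopulation can be empty by chance.  Ties at 100% between the triple
and its supersets resolve to the triple (enumeration order prefers the
smaller subset).  This is a simulator convention that makes the search
verifiable; it is not a claim about real faces, and the measured ~100%
rate on the synthetic cohort is a property of the construction, not a
reproduction of any empirical accuracy.

**What the synthetic cohort does not emulate.**  Real spatial texture
(the fields are stationary smooth surfaces with hard ROI plateaus),
motion/registration artifacts in the cohort maps (those are exercised
separately through the deformation generator), illumination drift,
inter-ROI physiological correlations beyond the global PS sign, and any
demographic structure.  Passing tests therefore demonstrate that the
pipeline recovers what its own forward models inject at realistic noise
levels — not that the classifier would reach these rates on real data.

## Numerical choices and degenerate inputs

* Attenuation at non-positive reflectance → NaN under the mask.
* All-invalid spectra yield an invalid fit object, not an exception.
* Hemoglobin-sum floor 1e-6 avoids 0/0 saturations.
* Warp design matrices are rank-checked; collinear landmarks raise.
* ROI means need ≥ 50% valid pixels; otherwise NaN.
* Boxplot summaries require ≥ 5 values.
* CV requires at least as many samples per class as folds.
* Subset ties in the search resolve to the first row in by-size,
  lexicographic order (the most parsimonious of the tied subsets).
* Problem sizes in the bundled checks: inversion at 64 × 64 pixels,
  cohorts at the full 513 × 911 canvas for layout/end-to-end runs and at
  64 × 114 (same aspect ratio) for the 200-replicate t-test calibration;
  searches use 5 folds × 10 repeats.

## Known limitations

* The extinction basis is analytic, not compiled literature data;
  absolute chromophore amounts are in arbitrary units.
* The default ROI rectangles are qualitative stand-ins for unpublished
  outlines; real analyses should supply measured geometry.
* The standard-face landmark layout is synthetic; registration accuracy
  on real faces depends on the quality of supplied landmarks.
* The 127-subset search reports selection-biased maxima by design; no
  correction is applied, only a caveat.
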