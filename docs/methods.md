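# Methods

## Scope and data model

`deltarad` analyses paired pre/post-treatment CT volumes of a single liver
lesion per patient, with a binary mask on the same voxel grid, plus a
clinical table (overall survival in months, death indicator, RECIST-style
response label, age, race, baseline tumor volume). Volumes are stored with
array axes (x, y, z) and spacing in mm; masks must match their volume's
grid exactly — no resampling is performed, and grid consistency is checked
on every pairing. HU outside [−1024, 3071] are clipped with a warning
(scanner artifacts), not rejected. Texture is strictly 2D: maps are
computed per axial slice and pixels are pooled across slices before
summary statistics, so slice thickness (1–3 mm typical) enters only
through which voxels exist, not through 3D offsets.

## Region construction

The peritumoral rim is the set of voxels whose Euclidean distance to the
tumor — computed with an anisotropic-sampling distance transform, so a
12 mm rim is 12 mm in every direction regardless of slice thickness — is
in (0, 12 mm], minus any voxel with HU ≤ −10. The HU rule removes
peri-hepatic fat ([−100, −10] HU) and, deliberately, air and lung, which
are lower still. `rim_mm` and the fat ceiling are configurable; an empty
rim after exclusions is flagged and all rim features become missing (never
silently zero).

## Texture bank

111 filters produce per-pixel response maps per slice:

* **Haralick (13).** The slice is quantized to 64 equal-width levels over
  the region's intensity range (a constant region maps to one level).
  Each region pixel's GLCM pools the symmetric co-occurrence pairs, for
  the four distance-1 offsets, whose both endpoints lie inside a centred
  5×5 window intersected with the region; the 13 classical features (ASM,
  contrast, correlation, variance, inverse difference moment, sum
  average/variance/entropy, entropy, difference variance/entropy, IMC1,
  IMC2) are evaluated on that local distribution. Logs are base 2 with
  0·log 0 := 0; correlation is 0 when a marginal is degenerate; sum
  variance is taken about the sum average. Pixels whose window holds no
  valid pair are missing. The region-level primitive `compute_glcm`
  (one matrix per offset, features averaged over offsets) uses the same
  formulas and is verified exactly against a brute-force pair-enumeration
  oracle.
* **Laws (25).** Raw responses to the 5×5 outer-product kernels of
  L5 = [1,4,6,4,1], E5 = [−1,−2,0,2,1], S5 = [−1,0,2,0,−1],
  R5 = [1,−4,6,−4,1], W5 = [−1,2,0,−2,1]; no energy windowing, since the
  five regional statistics already aggregate.
* **Laws-Laplacian (25).** The slice is first convolved with an analytic
  Laplacian-of-Gaussian kernel (σ = 1 px, truncated at 4σ,
  mean-subtracted so its sum is exactly zero and constants respond 0),
  then the Laws bank is applied.
* **Gabor (48).** Magnitudes of complex Gabor responses for 8
  orientations (steps of π/8) × 6 wavelengths {2,4,6,8,10,12} px, with
  σ = 0.56·wavelength and DC-corrected kernels.

All convolutions use reflect padding to avoid artificial edges at crop
borders. Each map's pixels, pooled over all annotated slices, are
summarized by mean, median, SD (n−1 denominator), skewness and excess
kurtosis (biased standardized-moment estimators); pools with zero range —
including near-constant pools where the moment computation loses
precision — report SD = skewness = kurtosis = 0 by convention. That gives
111 × 5 = 555 statistics per region and 1110 over tumor + rim. Filter
settings are hashed into the output for provenance.

## Shape descriptors

24 descriptors of the 3D mask in physical units, the exact list frozen in
`shape.py`: volume (mL), mesh surface area, surface-to-volume ratio,
sphericity, two compactness variants, maximum 3D diameter, maximum 2D
diameter in each principal plane, three PCA axis lengths (4√λ),
elongation, flatness, equivalent-sphere diameter, three bounding-box
extents, extent fraction, center-of-mass offset, slice count, mean slice
area, and the perimeter of the largest slice. Surface area comes from a
marching-cubes mesh of the mask after light Gaussian smoothing (σ = 0.5
voxel); the smoothing suppresses the staircase-surface inflation of
meshing a binary mask and was calibrated on digitized spheres, where the
meshed area then sits within ~4% of the analytic value (sphericity
0.96–0.98 for radii 5–12 voxels, capped at 1.0). Single-voxel masks fall
back to the unsmoothed mesh.

## Normalization and deltas

Normalization statistics (per-feature mean, SD) are fit on the pooled
pre+post values of the training cohort only, and reused unchanged on
validation data; validation column means are therefore generally nonzero,
which the tests assert as the no-leakage property. Features constant on
the training pool cannot be z-scored; the fitter drops and logs them, and
the pipeline retains them centred-but-unscaled so the delta pool keeps its
full 1110-column width (their training deltas are identically zero and
carry no selectable signal). Deltas are post − pre after normalization;
a config switch allows delta-then-normalize for sensitivity analyses. Raw
volume change (mL) is appended as its own column.

## Survival modelling

`fit_lasso_cox` wraps a coordinate-descent elastic-net Cox path solver
(pure L1) over a 100-point log-spaced grid spanning
[λ_max, 0.001·λ_max]. λ is chosen by k-fold cross-validation with
k = min(n_folds, n) — leave-one-out when the cohort is smaller than the
requested fold count. The default criterion is the held-out
partial-likelihood deviance (Verweij–van Houwelingen: the full-data
likelihood at the fold coefficients minus the training-fold likelihood);
a literal mean-squared-error reading is not well defined for a Cox model,
so a mean-squared martingale-residual criterion is provided as
`cv_criterion="mse_linear_predictor"` for fidelity experiments. The
solver tolerance defaults to 1e-5, which leaves selection unchanged on
the planted-signal benchmarks while fitting an order of magnitude
faster than the library default.

The RRS cutoff is the training-cohort median; ties at the cutoff go to
low risk (conservative). Kaplan–Meier curves, the log-rank test and
median survival come from standard product-limit machinery; Cox fits use
Efron tie handling with Wald intervals; Harrell's C credits 0.5 to tied
scores. Validation cohorts are always scored with the training cutoff and
training normalization — the train/validation firewall is asserted in
tests.

## Nomogram, calibration, decision curves

The nomogram Cox model covers RRS, age, binary-encoded race and baseline
tumor volume; each covariate's points are |β|·(x − x_ref) rescaled so the
widest swing spans 100 points, and total points map through the baseline
survival estimate to P(survive 36 months). The pipeline fits it with a
small ridge penalty (0.1) for stability on small cohorts. Calibration
bins predicted horizon event probabilities into deciles (empty bins merge
with a warning) and compares each bin's mean prediction to the
Kaplan–Meier event probability at the horizon — the censoring-aware
substitute for the binomial observed proportion in the classical
Hosmer–Lemeshow statistic, χ² = Σ n_g (o_g − p̄_g)²/(p̄_g(1−p̄_g)) with
groups−2 df. Overfitting is quantified by bootstrap optimism of the
C-index (default 500 resamples; every resample is recorded, failures as
NaN). Decision curves use NB(t) = TP/n − FP/n·t/(1−t) on a 0.01–0.99
threshold grid against treat-all and treat-none; horizon outcomes exclude
patients censored before the horizon.

## Response classification

Responder (CR/PR/SD) vs non-responder (PD) is predicted by a
pooled-covariance linear discriminant with automatic shrinkage of the
covariance estimate, so p ≥ n and duplicated columns are handled.
Training performance is the mean AUC over 100 independent random
stratified threefold partitions (each iteration pools its out-of-fold
scores into one AUC; the full trace is kept). The operating threshold is
the Youden index on training scores and is never recomputed on holdout;
holdout AUC carries a DeLong 95% CI. The classifier consumes the
LASSO-selected delta features by default; a baseline-features-only mode
runs the same machinery on pre-treatment features alone.

## Synthetic cohorts

The generator emulates contrast-enhanced abdominal CT of liver
metastases: liver background N(60, 10) HU, an ellipsoidal lesion
(radii 6–12 mm, mean 90 HU) centred in a 64×64×24 grid at (1, 1, 3) mm,
and an optional ~4 mm fat slab with HU uniform in [−100, −10] against the
lesion's +x face so rim fat exclusion is exercised. The lesion interior
carries white noise convolved with a Gaussian of 2 mm correlation length,
standardized to a planted amplitude: uniform 5–15 HU pre-treatment, with
a N(0, 5 HU) post-minus-pre change. The standardized change z is the
planted delta-heterogeneity; survival is T ~ Exp(h₀·e^{βz}) with
h₀ = ln 2/20 per month (≈20-month baseline median, matching the poor
prognosis of this population) and β the configurable effect (default 1);
response is non-responder iff z exceeds the responder threshold (default
0), so rising post-therapy heterogeneity marks non-response. Censoring
indicators are Bernoulli(censoring_rate) with censoring times uniform
below the event time, giving exactly the configured rate; a uniform
administrative scheme was rejected because its realized rate would drift
with the hazard. HU are rounded to integers and every draw runs through
seed-sequence streams keyed by (seed, patient, timepoint), so cohorts are
bit-for-bit reproducible and the clinical table can be regenerated
without the images (`generate_clinical_truth`) for many-replicate
statistical checks.

What the phantoms do *not* model: anatomy, scanner noise spectra and
reconstruction kernels, registration error between timepoints,
multi-lesion disease, and any correlation structure between texture and
shape. Passing tests therefore demonstrate that the pipeline recovers
planted effects under its own generative assumptions — a software and
statistical-calibration guarantee, not clinical validity.

## Problem sizes and numerical choices

The bundled demo configuration uses 12 patients (10 training, 2 held
out), chosen so a full simulate-to-classify run finishes in about a
minute; statistical checks that need replication (type-I error of the
median-split log-rank, LASSO recovery rates, LDA separation) run on
tabular cohorts of 100–200 patients where the images would add nothing.
The pipeline caches each stage in a content-addressed directory keyed by
the configuration it depends on, so changing the rim width rebuilds
regions and models but not phantoms; all outputs embed the stage hash,
package version and seed, and identical configs reproduce byte-identical
files.

Known limitations: the rim is not clipped to a liver mask beyond the HU
rule; texture is 2D only (no z-offsets, wavelets or fractal families);
no scanner harmonization; proportional hazards and exponential survival
are assumed throughout the synthetic checks; with two held-out patients
the demo's validation statistics are illustrative only.
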