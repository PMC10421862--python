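# deltarad

Delta-radiomics of CT liver lesions under CDK4/6-inhibitor therapy.

Patients with hormone-receptor-positive metastatic breast cancer and liver
metastases have a short expected survival, and no imaging biomarker tells
oncologists early whether endocrine therapy plus a CDK4/6 inhibitor is
working. `deltarad` implements the full quantitative-imaging pipeline for
that question: it extracts intratumoral and peritumoral CT texture features
before and after treatment, models the *change* in those features against
overall survival and RECIST response, and evaluates the resulting models the
way a clinical biomarker study would. Because patient scans cannot be
shipped with code, the package includes a synthetic phantom cohort generator
that plants known texture changes and couples them to survival, so every
stage is testable end to end.

It is aimed at imaging and biostatistics researchers who want a reproducible
reference implementation of a delta-radiomics survival pipeline, or a
harness for methodological experiments on one.

## What it computes

**Features.** For each scan, the lesion mask defines the intratumoral
region; dilating it by 12 mm in physical space and removing voxels at or
below −10 HU (peri-hepatic fat lies in [−100, −10] HU) defines the
peritumoral rim. On every annotated axial slice, 111 per-pixel response
maps are computed: 13 Haralick features from sliding-window gray-level
co-occurrence matrices (64 levels, four distance-1 offsets, symmetric,
base-2 logs), 25 Laws maps (outer products of L5/E5/S5/R5/W5), 25
Laws-Laplacian maps (Laplacian-of-Gaussian smoothing, then Laws), and 48
Gabor magnitude maps (8 orientations × 6 wavelengths). Pooling each map's
pixels across slices and summarizing with mean, median, SD, skewness and
excess kurtosis yields 555 texture statistics per region — 1110 across both
regions — plus 24 shape descriptors of the 3D mask.

**Deltas and risk score.** Features are z-scored with training-cohort
statistics and differenced (post − pre). LASSO-penalized Cox regression
over the 1110 texture deltas selects prognostic features; the radiomic risk
score is the linear predictor

RRS_i = Σ_j β̂_j x_ij,

with λ chosen on a 100-point log grid by k-fold cross-validated partial-
likelihood deviance. Patients are split at the training-median RRS and
evaluated with Kaplan–Meier curves, the log-rank test, hazard ratios from
Cox fits (Efron ties), and Harrell's C-index.

**Clinical utility and response.** A Cox model over {RRS, age, race,
baseline tumor volume} is laid out as a 100-point nomogram for 3-year
survival, with decile calibration (Hosmer–Lemeshow against Kaplan–Meier
observed proportions, 500-resample bootstrap optimism) and decision-curve
analysis, NB(t) = TP/n − FP/n · t/(1−t). A pooled-covariance linear
discriminant predicts responder vs non-responder from the selected delta
features, scored by 100 iterations of stratified threefold cross-validation
and a frozen-threshold holdout evaluation.

## Worked example

`examples/` holds one short script per capability. The survival-modelling
example plants 3 prognostic delta features among 200 noise features in a
200-patient cohort, selects on one half and validates on the other:

```sh
$ python examples/03_risk_score_survival.py
lambda = 0.1289; selected 7 features:
  planted0, planted1, planted2, noise75, noise103, noise134, noise176
validation C-index = 0.84
RRS hazard ratio = 4.28 (95% CI 3.25-5.64), p = 5e-25
median survival: high-risk 2.1 vs low-risk 81.3 months (log-rank p = 1.7e-22)
```

All three planted features are recovered (with a few small-coefficient
noise passengers, as expected for LASSO at this n), the held-out
concordance of 0.84 means the risk score orders survival times well, and
the median-split groups separate sharply. The other examples cover phantom
simulation, feature extraction, nomogram/DCA, and the response classifier.

An end-to-end run from one config — simulate → extract → delta → model →
evaluate, with per-stage caching and full provenance — is available as a
library call (`deltarad.run_pipeline`) or a thin CLI:

```sh
deltarad run-all --out-dir runs --seed 0 --n-patients 12
```

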