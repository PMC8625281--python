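# Methods

`lesionmap` implements a complete pretreatment lesion-location analysis for
acute anterior-circulation ischemic stroke: ADC-threshold segmentation,
atlas-based regional quantification, hemisphere-level cohort statistics, and
machine-learning prediction of dichotomized 3-month functional outcome.
Because trial-grade patient imaging is not redistributable, the package
ships a fully seeded synthetic cohort generator whose defaults encode the
cohort structure the analysis assumes; every empirical statement below is
computed by the test suite or by `scripts/acceptance.py`, not asserted.

## Segmentation

Acute ischemia restricts water diffusion, depressing the apparent diffusion
coefficient (ADC). A voxel is called ischemic iff it lies inside the brain
mask and its ADC value is **strictly below 615** (units of 1e-6 mm^2/s
throughout; NIfTI stores no intensity units, so ADC files are written with
a JSON sidecar stating them). No intensity normalization or bias-field
correction is applied: ADC maps are quantitative and the threshold is
absolute. The manual mask verification that a clinical workflow would add
is not reproducible in software; a small deterministic connected-component
filter stands in for it (default: remove 6-connected components smaller
than 5 voxels; both parameters exposed). The filter is idempotent and the
pre-cleanup mask is monotone in the threshold. A nearest-neighbour affine
resampler is provided for grid changes; nonlinear spatial normalization is
out of scope, since synthetic data are generated directly in atlas space.

## Regional quantification

For each atlas region *r* the ischemic percentage is

    pct(r) = 100 * |lesion ∩ voxels(r)| / |voxels(r)|,

i.e. the **fraction of the region that is infarcted**, not the fraction of
the lesion lying in the region. Region-size normalization keeps features
comparable across regions of very different volumes, which is the
convention of the lesion-symptom-mapping literature; the integer identity
`sum_r pct(r)·|voxels(r)|/100 = |lesion ∩ atlas-covered voxels|` holds
exactly and is enforced by tests. Gray- and white-matter parcellations are
applied independently, so a voxel may contribute to one region of each
tissue class. Regions listed in a label table but absent from the grid are
dropped with a warning rather than imputed as zero. Lesion volume is voxel
count × voxel volume / 1000 (mL). Hemisphere is assigned by strict majority
of lesion voxels over atlas hemisphere labels, ties going to left with a
warning; midline labels do not vote.

## Cohort statistics

Continuous variables are gated by the Shapiro–Wilk test at α = 0.05:
mean ± SD if normality is not rejected, otherwise median (Q1–Q3) with
type-7 (linear-interpolation) quantiles — stated explicitly because IQR
endpoints depend on the convention. Group comparisons between left- and
right-hemisphere strokes use the two-sided Wilcoxon rank-sum test
(exact distribution for group sizes ≤ 25 without ties, normal approximation
with tie correction otherwise) for continuous variables and the chi-square
test for categorical ones. Yates continuity correction is **off by
default** and available by flag: published tables do not always state which
variant they used, and the flag lets users match either convention.
Missing data are handled per-variable complete-case, so denominators may
differ across rows and are reported as n/N. Percentages are computed with
exact rational arithmetic and rounded half-up to two decimals.

## Outcome prediction

The positive class is **poor outcome** (mRS 3–6); identifying likely poor
outcomes is the clinical target. This is a config flag, as is the decision
threshold (0.5 on probability for logistic regression, 0 on the decision
value for the SVM).

Four model specifications:

| model      | features                         | selection            |
|------------|----------------------------------|----------------------|
| LogReg-Mp3 | age, NIHSS, lesion volume        | none                 |
| SVM-Mp3    | age, NIHSS, lesion volume        | none                 |
| LogReg-Mp4 | Mp3 + all regional percentages   | LASSO (embedded L1)  |
| SVM-Mp4    | Mp3 + all regional percentages   | F-score ranking + F1 curve |

Features are z-scored with training-fold statistics (required for the RBF
kernel and for LASSO comparability). The SVM ranking uses the Fisher
criterion

    F(j) = ((x̄⁺_j − x̄_j)² + (x̄⁻_j − x̄_j)²) / (s²⁺_j + s²_j⁻),

the standard univariate companion to LIBSVM-style workflows; features are
then added in rank order and the retained count is the argmax of
inner-cross-validated validation F1 (smallest count on ties). The training
side of that curve is only needed for plotting and can be skipped inside CV
loops.

Evaluation is stratified 10-fold cross-validation with fresh random
partitions per repeat; **all** standardization, selection and
hyperparameter search happen inside each training fold, and pooled
validation predictions give one panel (accuracy, sensitivity, specificity,
PPV, NPV, Mann–Whitney AUC with ties counted ½, F1) per repeat, summarized
as mean ± SD over repeats. Selection always runs in-fold — a single
selection on all data would leak validation information into the reported
panels — but the `fit` command additionally writes a whole-dataset
F1-vs-feature-count curve for plotting, clearly separated from the
cross-validated results. Repeat *r*
uses seed `base_seed + r`, so any repeat is independently reproducible, and
identical inputs give bit-identical results. Ratios with zero denominators
propagate as missing and are excluded from mean ± SD with a logged count.
Models sharing a partition schedule are compared by paired two-sided
Wilcoxon signed-rank over per-repeat AUCs (and accuracies); identical
results return p = 1. `folds == n` is honoured as leave-one-out, the one
case where stratification is impossible by construction.

Hyperparameter defaults follow common SVM practice — C ∈ {2⁻³, 2⁻¹, …, 2⁷}
and γ ∈ {2⁻⁷, 2⁻⁵, …, 2³} by inner 5-fold grid search; LASSO strength over
a 5-point log grid — but every simulation study in the tests and the
acceptance script uses the `desk_scale()` preset (fixed C = 1, γ = 'scale',
3-point LASSO grid, 3 inner folds, feature curve capped at 25 candidates),
chosen once so a full study runs on a single CPU in minutes. The full grids
remain the documented defaults for real analyses.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, with
defaults fixed as the package's study conditions:

- **Cohort**: 143 patients; 32³ grid at 3 mm isotropic voxels (ellipsoidal
  brain ≈ 340 mL) with an even first axis so an exact mid-sagittal plane
  exists; left hemisphere at negative world x via a diagonal RAS affine.
- **Atlas**: 16 gray-matter + 7 white-matter regions per hemisphere
  (46 total), built by multi-source breadth-first growth from random seeds
  within each tissue class of the left hemisphere and mirrored to the
  right, giving contiguous, 6-connected, left/right-paired regions that
  exactly partition the brain. White matter is an inner ellipsoidal core.
- **Lesions**: one per patient, confined to one hemisphere, grown from a
  random in-brain voxel by uniformly absorbing 6-connected boundary voxels
  until a log-normally drawn target volume (median 20 mL, log-SD 1.0 — a
  compromise within the skewed interquartile range typical of thrombectomy
  cohorts) is reached; targets exceeding the hemisphere are truncated and
  flagged. Region growing produces contiguous irregular shapes without
  modeling vascular territories, which nothing downstream requires.
- **ADC**: lesion voxels N(450, 50), other voxels N(850, 60), clipped at 0.
  These satisfy the separability contract at the 615 threshold (≥ 95% of
  lesion voxels below it, ≤ 5% of normal brain voxels below it) with wide
  margin; with both SDs at 0 thresholding recovers truth voxel-exactly.
- **Covariates**: age ~ N(64, 12) truncated to [18, 80]; NIHSS ~ discrete
  uniform 10–25 (the usual thrombectomy-trial inclusion range).
- **Outcomes**: poor-outcome indicator ~ Bernoulli(σ(η)) with
  η = −0.2 + 0.5·z(age) + 0.8·z(NIHSS) + Σ β_r·z(pct_r); covariates are
  standardized against the generated sample so betas are on a common scale.
  The planted-effect preset puts β = 2.0 on 5 regions spread over
  hemispheres and tissue classes. The latent η is recorded per patient for
  diagnostics.

All randomness flows from one seed sequence: identical config + seed gives
bit-identical cohorts, including across processes.

### What the generator does and does not emulate

It reproduces the statistical skeleton — lesion contiguity and laterality,
ADC contrast, skewed volumes, covariate ranges, a logistic outcome model —
but not vascular-territory anatomy, partial-volume effects at lesion
borders, scanner/field-strength variation, registration error, or
atrophy. Passing tests therefore demonstrate correctness of the pipeline's
computations and the recoverability of planted signal under clean
conditions, not clinical performance on real imaging.

One emergent property matters for interpretation: because lesions are
contiguous, the regional percentages of **adjacent** regions are strongly
correlated, so in fully volumetric cohorts selection credit for an
outcome-relevant region spreads to its neighbours — the regional model's
AUC advantage is unaffected, but region-level attribution blurs. This
mirrors real lesion-symptom mapping, where co-infarcted regions within one
vascular territory are hard to disentangle. The planted-support recovery
studies therefore use feature-level tables with independent regional
percentages; the volumetric ΔAUC is reported by the acceptance script.

## Numerical choices and degenerate inputs

- Threshold ties: a voxel at exactly 615 is *not* ischemic (strict `<`).
- Constant vectors: normality is undefined; the median form is reported
  with a warning. Zero-variance features z-score to 0.
- Fisher scores with zero within-class variance in both classes rank above
  all finite scores, ordered by between-class difference, with a warning.
- Empty lesions: volume 0, all percentages 0; hemisphere assignment raises
  rather than guessing.
- Seeds are kept below 2³¹ wherever sklearn consumes them.

## Problem sizes used by the shipped studies

The simulation studies are sized to run on one CPU: null calibration uses
n = 150 cohorts over a 12-region atlas, 10 seeds × 20 repeats; planted-
effect recovery uses n = 150 feature tables with 50 regions, 20 seeds × 3
repeats; the acceptance script runs the full volumetric pipeline at
n = 143 with 10 repeats. The repeated-CV protocol itself defaults to 10
folds and is typically run with 100 repeats in a full analysis; the
pipeline demo config defaults to 20.

## Known limitations

- The atlas is a geometric stand-in: mirrored compact parcels, not AAL/JHU
  anatomy, and no midline structures.
- Lesion growth ignores vascular territories and white/gray boundaries.
- The "semi-automatic" human editing step of clinical segmentation is
  represented only by the component-size filter.
- SVM decision values pooled across folds are not calibrated probabilities;
  AUC and rank-based comparisons are unaffected, but threshold-based
  metrics at 0 inherit fold-to-fold offset noise.
- With strong planted effects a near-perfect SVM is insensitive to extra
  noise features, so the argmax-F1 feature count can overshoot the true
  support; the selected set still contains it.
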