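# Methods

This note documents the models, numerical choices and limitations of
cortexfuse, in the order the pipeline runs.

## Volumetric stage

**Coordinate conventions.** Voxel indices are 0-based; the 4×4 affine maps
voxel index to world mm (NIfTI semantics). All surface sampling happens in
world coordinates; volumes only need to share an affine, not a grid shape,
although the phantom generates everything co-registered on one grid.
Co-registration itself (MRI↔PET rigid alignment, template registration,
tissue classification, surface extraction) is upstream of this package:
segmentations and surfaces are inputs.

**Weighted PVE.** `wPVE = 1.0·GM + 0.25·WM + 0.0·CSF`. The weights encode
that CSF takes up no tracer and WM uptake is about one fourth of GM uptake;
they are fixed constants of the model, not fitted. Tissue-fraction sums
slightly above 1 (upstream estimators overshoot) are renormalized with a
warning rather than rejected.

**PET-resolution matching.** The wPVE volume is smoothed with a 6 mm FWHM
isotropic Gaussian (σ = FWHM / (2√(2 ln 2)) per axis, in voxel units per
axis for anisotropic voxels) before surface sampling, so that the tissue
model sees the same point-spread as the PET data. The PET/DVR volume itself
is sampled unsmoothed. Boundary handling is zero padding; all test and
phantom signals keep at least two PSF widths of margin, so the choice is
inert there, but users smoothing signal near the grid edge should be aware
values shrink toward zero.

**DVR normalization.** The paper-level "distribution volume ratio" image is
produced upstream by kinetic modeling of dynamic frames; here DVR
normalization is implemented as static reference-region scaling — every
voxel divided by the mean uptake inside the cerebellar mask, giving a
cerebellar mean of exactly 1. The operation is idempotent and makes csFDG
invariant to any global PET gain.

## Surface stage

**Data model.** A cortical hemisphere is a `SurfacePair`: inner (WM/GM) and
outer (GM/CSF) triangle meshes with identical topology and linked vertices.
Thickness is t-link: the Euclidean distance between linked vertices. No
alternative thickness metrics are provided.

**Profiles.** Each linked segment is divided into five equal proportions,
giving 6 sample points including both boundary vertices; each point is
trilinear-interpolated from the volume. The surface value is the arithmetic
mean of the 6 samples — the mean, not the maximum of earlier surface-PET
work, so that uptake and tissue maps are collapsed by the same linear
functional and their ratio cancels the partial-volume response. (The
6-point mean is the trapezoid-rule integral mean up to endpoint weighting;
this is a documentation note, not an asserted identity.) Out-of-bounds
sample points raise, naming the vertex; there is no silent extrapolation.

**Diffusion smoothing.** Heat diffusion on the mesh graph with the
cotangent-weighted Laplacian and lumped (barycentric) vertex areas,
integrated by iterated explicit Euler steps for a total time
t = FWHM² / (16 ln 2), the standard FWHM↔time relation for heat kernels.
Numerical choices:

* negative cotangent weights (obtuse triangles) are clamped to zero, so
  every explicit step is a convex combination of neighbour values — this
  guarantees the discrete maximum principle at the cost of a slightly
  perturbed operator on poor-quality meshes;
* the step size is half the stability bound min_i(area_i / degree_i), and
  at least 100 steps are taken so the first-order time-discretization error
  stays below ~1% (verified against the exact matrix exponential of the
  same operator);
* the lumped-mass formulation conserves the area-weighted integral exactly
  (up to float rounding), matching heat-kernel semantics on irregular
  meshes.

**csFDG.** Both sFDG and swPVE are smoothed with the 20 mm FWHM kernel
before division. Dividing a smoothed numerator by an *unsmoothed*
denominator would reintroduce the high-frequency PVE pattern the correction
is meant to remove; the alternative reading is still available via
`smooth_target="numerator"`. Vertices whose smoothed swPVE falls below 0.05
(5 % effective tissue) are flagged NaN rather than divided, and excluded
from regional means; if more than 10 % of vertices fall below the floor the
tissue model is considered broken and the correction raises.

**Regional means** are plain vertex means by default (an area-weighted
option exists behind a flag); region id 0 is reserved for "unlabeled".
Whether the original regional means were vertex- or area-weighted is not
derivable from the method description; unweighted is the default because it
is the plain reading of "mean".

## Features

The lexicon holds 39 cortical regions plus the hippocampus. Only the 12
predefined AD-associated regions are fixed by the method; the remaining 28
cortical names complete the lexicon with standard anatomical region names.
Feature sets: SMF (12 predefined × 2 modalities = 24), SSF (12, one
modality), whole-brain (80), volume-based (24: ICV-normalized regional GM
volumes plus masked PVC uptake), and hippocampal volume/uptake.

**Data-driven selection** ranks regions by two-sample |t| (pooled variance;
Welch optional) and keeps the top 12 with ties broken by region name. The
per-region score is the maximum |t| across the region's modalities, so a
selected region contributes both its MRI and FDG features, mirroring the
12 × 2 structure of the predefined set. By default selection is refit
inside every LOOCV training fold (leakage-safe); `select_once` reproduces
the single-shot reading in which the held-out subject influences its own
feature set. Subjects with flagged regional values are dropped from a
comparison rather than imputed.

## Classifier

**PLS.** Sequential NIPALS on mean-centered X and 0/1 y: per component the
weight is w_a ∝ Xᵀy, the score t_a = X w_a, and X and y are deflated by
their rank-one reconstructions. For a univariate response the y-block score
u_a is the running y residual, so the inner coefficient β_a of
u_a = β_a t_a is the regression of y on t_a. Scores are exactly orthogonal;
at full rank the PLS regression reproduces ordinary least squares.
Components beyond the numerical rank are dropped with a warning. Features
are centered but not autoscaled by default (autoscaling is available and
matters when mixing mm and uptake units).

**PRESS.** The component count K minimizes the exact leave-one-out
prediction residual sum of squares; one PLS fit per left-out observation
supplies all nested truncations, ties break to the smallest A. Under pure
noise K = 1 is selected in about three quarters of runs — argmin-PRESS
retains a modest false-component rate, which is why LOOCV of the full
pipeline (including PRESS) is the honest performance estimate.

**LDA.** Class means and pooled within-class covariance on the training
scores, equal priors by default (empirical optional). A ridge floor of
1e-8·trace/K is added when the condition number exceeds 1e8; tiny LOOCV
classes can otherwise degenerate. A new observation goes to the class with
the smaller Mahalanobis distance. Printed versions of this rule sometimes
carry an argmax over the quadratic form, which would assign the *farther*
class; argmin is the standard and implemented choice. The discriminant
score D(class 0) − D(class 1) (positive favoring the impaired class) feeds
the ROC; exact ties go to class 0.

**Validation.** LOOCV refits everything — PRESS and, if enabled,
data-driven selection — on each fold of N−1 subjects. The positive class of
a pair is the more impaired diagnosis (AD in AD/NC and AD/MCI, MCI in
MCI/NC); this is the only convention under which sensitivities are integer
multiples of 1/n_positive. AUC is the trapezoidal area of the threshold
sweep and equals the Mann–Whitney concordance (ties counted half). The
logistic screen fits outcome ~ intercept + feature per feature by IRLS,
reporting Wald standard errors and p-values (no multiple-testing
correction) plus the AU-ROC of fitted probabilities; perfect separation is
flagged explicitly instead of reporting runaway coefficients.

## Synthetic data

**Imaging phantom.** A spherical-shell cortex: inner surface at a fixed
radius (default 20 mm), outer surface one thickness further out (default
3 mm), 39 regions as spherical Voronoi cells of Fibonacci-spread seed
directions, with per-region thickness and uptake configurable. Tissue
fractions come from 3³-per-voxel supersampled occupancy (configurable);
noise-free activity is u·GM + 0.25·u·WM, convolved with the 6 mm PSF
Gaussian, plus additive Gaussian noise (default SD 0.01 in DVR units, a
mild noise floor after frame averaging). A separate cerebellar sphere with
uptake 1 provides the reference region (its mask eroded 7 mm so PSF
spill-out barely biases the reference mean); a hippocampal ellipsoid
(8×5×5 mm semi-axes) embedded in the WM core acts as the GM subcortical
structure; an intracranial sphere supplies ICV. Defaults: 64³ grid at 2 mm
voxels, 2562-vertex icospheres — one subject generates in a few seconds.

A spherical shell exercises profiles, PVE and smoothing exactly as a folded
cortex would and gives closed-form shell volumes as oracles, but it does
not reproduce sulcal geometry: opposing sulcal banks closer than the PSF,
partial-volume effects between touching gyri, and surface-extraction errors
are outside what passing phantom tests demonstrate. Likewise the phantom's
tissue fractions are exact by construction, so tests say nothing about
upstream segmentation error. Region borders are radial steps when
thickness differs between regions; the 20 mm surface kernel bleeds across
borders, which is why region-specificity tests use few, large regions.

**Feature cohorts.** Per-group multivariate Gaussians over the 24 SMF
features with exchangeable correlation ρ = 0.2 (a modest, realistic
regional-feature correlation), group sizes defaulting to the study cohort
(85 NC / 163 MCI / 71 AD), and mean shifts in SD units: AD −1.5 on the 12
MRI features, MCI half of that, NC at baseline. Shifts are negative for
patient groups, matching atrophy/hypometabolism. Per-feature baselines
(2.5 mm / 1.2 DVR) and SDs (0.25 / 0.12) give realistic units without
affecting the affine-invariant classifier. The Gaussian cohort has no
outliers, no site effects and no label noise, so classifier results on it
are upper bounds on real-cohort behaviour, not predictions of it.

## Problem sizes

Tests and the acceptance script run phantoms at the 64³ default (80³ for
the region-specificity case), oracle meshes at 642 vertices, null
calibrations at 100 cohorts of n = 60, and signal-recovery checks at 10
cohorts of n = 156 — sizes chosen so each check isolates one property at
comfortable statistical resolution.

## Known limitations

* No inter-subject surface registration: regional features assume a shared
  mesh topology or upstream registration.
* Binary comparisons only; the three-group problem is handled as three
  pairwise classifiers.
* The logistic screen reports raw Wald p-values; callers wanting
  family-wise control must correct externally.
* PRESS is exact-LOO and O(N²) in fits; fine for cohort sizes in the
  hundreds, not tuned for thousands.
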