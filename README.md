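# cortexfuse

Surface-based multimodal discrimination of Alzheimer's disease (AD), mild
cognitive impairment (MCI) and normal controls (NC) from structural MRI and
FDG-PET — as a reusable, fully synthetic-testable toolkit.

## Who this is for

Neuroimaging methods researchers who want the complete pipeline —
surface-based PET partial-volume correction, cortical-thickness features,
and a PLS-LDA classifier with leave-one-out validation — as an importable
library with known-truth digital phantoms, rather than as a site-specific
processing script. All inputs can be synthesized, so every stage is testable
without access to patient data.

## The method

**Partial-volume-corrected surface uptake (csFDG).** PET voxel intensities
in cortex are diluted by the partial volume effect (PVE): the cortical
ribbon is thinner than the scanner point-spread function, so GM signal mixes
with low-uptake WM and zero-uptake CSF. Given co-registered tissue fraction
maps (GM/WM/CSF) and linked inner/outer cortical surfaces:

1. normalize PET to the cerebellum (DVR units, cerebellar mean = 1);
2. build the weighted PVE map `wPVE = GM + WM/4` (CSF takes up nothing, WM
   about a quarter of GM) and smooth it with a 6 mm FWHM Gaussian to match
   PET resolution;
3. sample both volumes at 6 points per linked-vertex segment (fractions
   0, 0.2, …, 1 from the WM/GM to the GM/CSF vertex) and average, giving
   the surface maps `sFDG` and `swPVE`;
4. diffusion-smooth both maps on the mesh with a 20 mm FWHM heat kernel and
   divide: `csFDG = smooth(sFDG) / smooth(swPVE)`.

Where the tissue model says only 40 % of a GM-like signal could have been
observed, dividing by 0.4 restores the true uptake.

**Features.** Mean cortical thickness (t-link: Euclidean distance between
linked vertices) and mean csFDG over a 39-region cortical lexicon, plus
ICV-normalized hippocampal volume and PVC-corrected hippocampal uptake.
The default feature set (SMF) is 12 predefined AD-associated regions × 2
modalities = 24 features; alternatives are single-modality (SSF, 12),
whole-brain (80), volume-based (24), and data-driven top-12 regions by
two-sample |t|.

**Classifier.** NIPALS partial least squares extracts latent components
`X = TPᵀ + E`, `y = UQᵀ + F` with inner relation `u_a = β_a t_a` on the
0/1 class coding; the component count K minimizes the leave-one-out PRESS.
LDA with class means μ̂_g and pooled covariance Σ̂ assigns a new subject to
the class with the smaller Mahalanobis distance
`(T − μ̂_g) Σ̂⁻¹ (T − μ̂_g)ᵀ`. Validation is leave-one-out
cross-validation (selection refit per fold), with accuracy / sensitivity /
specificity, a ROC curve from the held-out discriminant scores, and a
per-region simple logistic regression screen.

## Worked example

```bash
python examples/01_phantom_pvc.py
```

```
true GM uptake (DVR units):     1.200
raw surface uptake, mean:       0.432 (-64.0% vs truth)
corrected csFDG, mean:          1.205 (+0.4% vs truth)
thickness regional means (mm):  2.000 (truth 2.000)
```

A 2 mm cortex under a 6 mm PSF loses almost two thirds of its apparent
uptake to the partial volume effect; the surface-based correction recovers
the true value to within half a percent, and the t-link thickness reads the
phantom's 2 mm ribbon back exactly.

```bash
python examples/02_classify_cohort.py
```

```
subjects: 156 (positive class: AD)
LOOCV accuracy:    98.7%
LOOCV sensitivity: 98.6%
LOOCV specificity: 98.8%
AU-ROC:            0.990
```

On a synthetic AD/NC cohort (85 NC / 71 AD, −1.5 SD patient shifts on 12 of
24 features) the pipeline reaches the performance its signal supports; each
subject is scored by a model that never saw it. The other examples cover
the logistic screen and data-driven region selection.

A thin CLI wraps the same library: `cortexfuse phantom | cohort | map |
features | train | evaluate | demo` (see `cortexfuse --help`).

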