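# Methods

`amypipe` quantifies amyloid burden from PET/MRI pairs under a factorial
family of image-processing pipelines and compares the resulting metrics
statistically.  Because real scans cannot ship with a software package, a
synthetic-cohort generator with exact ground truth is a first-class
component: every numerical claim in the test suite is checked against
quantities the generator knows analytically.

## 1. Image model

Volumes are 3-D scalar grids with a NIfTI-style 4×4 affine (0-based voxel
indices → world mm, RAS+).  Every image carries a value-semantics tag:

* **concentration** (intensive): MRI intensity, SUV, SUVR, probabilities.
  Unchanged by resampling.
* **amount** (extensive): produced by Jacobian-modulated warping; the sum
  over voxels approximates an integral and is conserved under deformation.

Rigid transforms are world-space maps `x → R x + t`.  Resampling pulls
values back (the output voxel at world `x` reads the moving image at
`T(x)`), with linear or nearest interpolation and an explicit validity
mask for voxels whose source point leaves the field of view.  Dynamic PET
series are averaged over a late time window with duration-of-overlap
weights, so unequal frame lengths form a proper time-weighted mean.

## 2. Phantom (synthetic cohort with ground truth)

### Template anatomy

The population template is analytic: an ellipsoidal "cerebrum" whose
radial coordinate ρ defines a cortical grey-matter ribbon (GM between
ρ = 0.70 and 0.90 of the ellipsoid, sigmoid edges of 1 mm width), white
matter inside it, CSF ventricles near the centre and a CSF shell outside,
plus a disjoint cerebellar ellipsoid (85 % GM / 15 % WM) placed
postero-inferior to the cerebrum.  Tissue probabilities sum to ≤ 1, the
remainder being background.  The template T1 is the probability-weighted
sum of class means (GM 80, WM 110, CSF 30).

The cortical ribbon is geometrically thin; at coarse voxel sizes its peak
GM probability is limited by partial volume (≈ 0.89 at 2 mm, ≈ 0.97 at
1.5 mm).  That is a property of the anatomy, not an artefact.

### Subjects

Each subject is derived from the template through a smooth, invertible,
subject-specific deformation (small random affine jitter plus
low-frequency separable-cosine displacements, amplitude 3 mm), a rigid
head pose (≤ 3 mm / 3°), and for AD subjects a *geometric atrophy* factor
(0.75–0.90) that thins the ribbon by moving its inner boundary outward —
atrophy changes anatomy, not just intensity.

The true tracer field is an SUVR map: cerebellar reference pinned to
exactly 1.0, white matter 1.1, CSF 0.35, healthy GM drawn per subject
(0.90–1.15).  AD subjects additionally carry four solid spherical lesions
(radius 9–14 mm) with SUVR drawn from 1.9–2.6, well above the 1.5
positivity threshold.  Lesion placement is rejected if it leaves the GM
capable region.

Observed data are generated forward: PET = `pet_scale` × SUVR field,
blurred with a 4 mm FWHM Gaussian PSF, Gaussian noise (σ = 5 % of scale),
and a small rigid PET-vs-MRI misalignment (≤ 2 mm / 2°); MRI = tissue
means + degree-2 polynomial bias field (±10 %) + Gaussian noise (σ = 4).

Ground truth retained per subject: the deformation field, tissue
probabilities, GM and cerebellum masks, the noiseless SUVR field, and the
metric set computed from them.  Per-subject seeds derive from the master
seed via a `SeedSequence` (reduced mod 2³¹), so cohorts are reproducible
and individual subjects can be re-synthesised in isolation.

Defaults are the study conditions: 12 AD + 16 HC subjects, 96³ voxels at
1.5 mm, threshold 1.5.  Grid size and spacing are free parameters; the
test suite uses 32³/48³ at 2 mm where a check does not depend on the
default resolution.

## 3. Spatial normalization

Two families of deformation estimators connect native and standard
(template) space.  A `DeformationField` stores pull-back displacements in
mm on the *destination* grid: `out(x) = src(x + d(x))`.

* **MAP** ("unified-segmentation-free" template matching): estimates the
  native→standard field on the template grid by minimising the sum of
  squared differences between the warped subject T1 and the template,
  over a 12-parameter affine plus a separable low-frequency cosine basis
  (5 modes per axis, constant mode dropped), with a frequency-weighted
  smoothness penalty (λ = 1e-5), a two-level Gaussian pyramid
  (6 mm → 0 mm) and L-BFGS-B.  If the Jacobian floor (0.05) is violated
  the penalty is boosted and the fit repeated (≤ 3 boosts).  The same
  estimated geometry is applied either **concentration-preserving
  (MAPc)** or **amount-preserving (MAPa**, Jacobian-modulated); the two
  share one warp by construction.
* **USM** (unified segmentation): alternates a prior-informed 4-class
  Gaussian-mixture tissue classification with cross-entropy-driven
  updates of a standard→native warp of the template priors, on the same
  cosine basis.  Warp updates are only accepted when the mixture
  negative log-likelihood does not increase, so the outer trace is
  monotone.

Warp inversion uses an undamped fixed-point iteration with nearest-mode
displacement sampling, judged converged at 0.45 voxels inside the field
of view.  Warp estimation runs on a decimated (~32³) evaluation grid for
speed; the resulting coefficients are evaluated on the full grid.

Rigid PET→MRI registration maximises normalised mutual information on a
30 000-sample Parzen soft histogram (48 bins), both images pre-smoothed
with a 4 mm FWHM Gaussian, optimised by two-stage Powell search.

## 4. Segmentation and VOI provisioning

Tissue classification is a Gaussian mixture over GM/WM/CSF/background
with optional spatial priors, histogram-mode M-steps, pooled per-class
variance floors, an optional multiplicative degree-2 polynomial bias
field (kept only when it lowers the NLL), and a deterministic k-means
initialisation — no hidden randomness.  Without priors, a head mask
(Otsu threshold, morphological closing, hole filling) separates
foreground, and classes are labelled by intensity order (CSF < GM < WM
for T1 contrast).

The partial-volume shell between the brain surface and air receives
CSF-like labels, as in real T1 segmentation; only the GM class is used
downstream.

Three GM definitions feed quantification: **MRn** (segment the native
MRI; warp the probability map when the analysis is in standard space),
**MRs** (warp the MRI first, segment in standard space; undefined for
native analyses), and **TEs** (template GM map, inverse-warped for
native analyses).  Probability maps are thresholded at 0.5 (inclusive)
*after* any warping.  The cerebellar reference VOI is the template VOI in
standard space, or its inverse-warped soft mask re-thresholded at 0.5 in
native space.

## 5. Quantification

SUVR = PET voxel value / mean PET over the cerebellar VOI (restricted to
valid voxels; an empty VOI or non-positive reference mean raises).  From
the SUVR image and a GM VOI, with positivity threshold *T* (default 1.5;
1.2 as a sensitivity setting):

| metric | definition |
| --- | --- |
| `suvr_mean` | mean SUVR over GM |
| `suvr_mean_abeta_pos` | mean SUVR over GM voxels with SUVR ≥ *T* (NaN if none) |
| `abeta_volume_ml` | volume of GM voxels with SUVR ≥ *T* |
| `afv` | amyloid fraction of volume: Aβ⁺ volume / GM volume |
| `tab_ml` | total amyloid burden: `suvr_mean_abeta_pos` × Aβ⁺ volume (NaN if no positive voxels) |

## 6. Pipelines

The factorial family is {native, standard} space × {MAPa, MAPc, USM}
transform × {MRn, TEs, MRs} GM definition, minus the undefined
(native, MRs) cell: 15 pipelines.  The two *main* pipelines are
(native, USM, MRn) and (standard, USM, MRn).  In native-space analyses
the PET is never warped non-rigidly, so MAPa and MAPc rows are
identical there by construction.

`PipelineRunner` estimates each warp once per (subject, transform
family) and caches GM VOIs and SUVR images per cell, so running both
thresholds or re-running single cells is cheap.  Per-subject caches are
evicted after each subject during cohort runs to bound memory.  Failures
(e.g. an empty reference VOI) are quarantined into `status="failed"`
rows with the error message; a majority of failures aborts the run.

## 7. Statistics

Cohort tables are analysed with Gaussian GEE (independence working
correlation, subjects as clusters, robust sandwich covariance) on a
reference-coded design with main effects and two-way interactions,
rank-reduced by QR.  Estimated marginal means average the prediction over
the observed factor grid; pairwise contrasts are reported in percent of
the second-named level, with 95 % CIs and tiered p-values (p < 0.001,
< 0.01, < 0.05, N.S.).  The standard battery covers space
(standard—native), the three transform pairs, TEs—MRn everywhere, and
the MRs contrasts in standard space only (MRs does not exist in native
space).  The two main pipelines are compared by per-subject paired
differences.  A cluster bootstrap of the contrast SE serves as an
independent check on the sandwich estimator.

## 8. Problem sizes

Grid sizes, subject counts and optimiser budgets used in tests and in
the acceptance script are this package's own choices, made to fit a
single CPU and a few GB of memory:

* unit tests of numerics: 32³ at 2 mm;
* integration and cohort-level checks: 48³ at 2 mm, full 28-subject
  cohort, all 15 pipelines (plus the 1.2-threshold repeat);
* default-condition checks (degenerate subject, parameter recovery):
  96³ at 1.5 mm, a few subjects only — a full 28-subject cohort at the
  default grid does not fit in a few GB of RAM together with a test run.

Tolerances are not tuned to the implementation: exactness claims are
asserted at machine precision in noise-free settings, and noisy-setting
bounds derive from the generator's own noise model (e.g. the PSF places
a floor of ≈ 5 % on single-subject SUVR bias at default blur).

## 9. Limitations

* The anatomy is a smooth parametric ellipsoid world: no gyrification,
  no skull/scalp intensity, no susceptibility or motion artefacts.
* The deformation class used for estimation (low-frequency separable
  cosines) matches the class the generator draws from; real inter-subject
  variability is richer, so registration accuracy here is an upper bound.
* PET noise is Gaussian and stationary rather than reconstruction-aware;
  the PSF is an isotropic Gaussian.
* Amyloid lesions are solid spheres with uniform uptake.
* The GEE analysis treats pipeline cells as fixed conditions; no
  between-scanner or test–retest variance component is modelled.
* With a 4 mm PSF and no partial-volume correction, single-subject SUVR
  recovery carries an irreducible blur bias; accuracy criteria are
  therefore posed on lesion-bearing subjects (lesion radii ≥ 8 mm) and on
  exact zero-burden recovery for amyloid-free subjects.
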