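# Methods

`murivol` re-creates, end to end, a volumetric comparison between
longitudinal *in vivo* and single-timepoint *ex vivo* structural MRI of a
three-group mouse cohort (wild-type controls, untreated tauopathy-model
transgenics with progressive forebrain atrophy, and drug-treated transgenics
with attenuated atrophy). Because no imaging data are distributed, the
package generates its own: a seeded synthetic cohort whose phantom images
carry, by construction, the statistical structure the downstream analysis is
supposed to detect. Every analysis stage then operates on those images
exactly as it would on real acquisitions.

## The generative cohort model

Per structure *s* and subject *i*, the true volume trajectory is linear in
age *t* (months):

    V_is(t) = β0 + β1·t + β2·g_i + β3·t·g_i + b1_is + b2_is·t + ε_ist

with `g` a severity code (wild-type 0, treated 0.5, untreated 1),
`b1 ~ N(0, σ_b1²)` a per-subject volume offset, `b2 ~ N(0, σ_b2²)` a
per-subject trajectory slope, and `ε ~ N(0, σ_ε²)` per-scan noise. This is
precisely the richest of the three mixed-effects models the analysis stage
fits, so model-recovery experiments are exact by design.

Defaults (see `murivol.cohort.default_structures`): an 11-structure catalog
with literature-plausible adult-mouse volumes (neocortex 110 mm³ …
anterior commissure 2 mm³, total ≈ 425 mm³), common growth `β1` of
0–0.3 mm³/month, severity-interaction atrophy `β3` of −0.01 to
−1.8 mm³/month per unit severity for gray matter and +0.55 for the
ventricles, and per-subject variability σ_b1 = 2%, σ_b2 = 1%/month,
σ_ε = 1% of the baseline volume. Group sizes default to 8 wild-type, 10
untreated and 7 treated; in vivo timepoints to 4.5/5.5/7.5 months (the
acquisition schedule; configurable because the source record is
inconsistent about the first age).

Terminal **ex vivo** volumes are the last in vivo volumes scaled by
tissue-class factors — GM ×0.92, WM ×1.08, CSF ×0.03 — emulating fixation
shrinkage of gray matter, white-matter swelling and near-total ventricular
collapse. Volumes are floored at 10⁻³ mm³ so the percentage volume
difference stays defined. The closed-form PVD of a multiplicative change
`f` is `200(f−1)/(f+1)`: −8.33% for GM, +7.69% for WM, −188% for CSF;
these are the recovery targets of the volumetric acceptance tests.

Random streams are keyed by `(seed, group, within-group index)`, so growing
a cohort never reshuffles existing subjects.

## Phantom rendering

Subjects are rendered as a fixed template of non-overlapping ellipsoids in a
11.7 mm field of view; bilateral structures are mirror pairs about the
mid-sagittal plane sharing one label. The template positions were solved
once so that worst-case study volumes keep every pair of ellipsoids ≥0.4 mm
apart. Per-subject anatomy varies only through the requested volumes (plus
an optional global linear scale emulating gradient drift, off by default);
this keeps label adjacency stable across the cohort, which is what a
template-consistent atlas pipeline assumes.

Volume accuracy: for each structure the renderer computes a 2× supersampled
in-ellipsoid occupancy per voxel and assigns exactly `round(V/voxel_volume)`
voxels in descending occupancy (quadratic-form tie-break), so rendered
volumes are correct to half a voxel — better than 1% above ~50 voxels and
essentially exact at 40 µm.

Intensities follow a T2-weighted-like contrast: GM 100, WM 70, CSF 130,
background 10, plus white Gaussian noise. Noise defaults are set from the
target tissue contrast-to-noise ratios: SD 30 in vivo (CNR ≈ 1.0) and SD 12
ex vivo (CNR ≈ 2.5). Default grids are 78³ at 150 µm (in vivo) and 292³ at
40 µm (ex vivo); the *fast* profile keeps the field of view and coarsens to
300/150 µm.

What the phantoms do **not** emulate: anatomy-shaped structures, partial
volume at tissue interfaces (labels are hard), bias fields (unless injected
to test the corrector), motion/ghosting, and spatially correlated noise.
A green phantom test therefore validates the *computational* chain, not
robustness to real-scanner artifacts.

Synthetic atlases are template renderings with per-structure volumes
jittered by `exp(N(0, 0.06))`, mimicking a small database of manually
labeled subjects; like the real database, the set exists in in vivo and
ex vivo variants (the latter with the wild-type ex vivo factors applied, so
atlas ventricles are collapsed too).

## Multi-atlas parcellation

Standard segmentation-propagation recipe: optional polynomial bias-field
correction (a least-squares log-domain stand-in for N4); global affine
registration (multi-resolution Powell search over translation/rotation/
log-scale maximizing a 32-bin normalized mutual information); non-rigid
refinement (cubic-B-spline free-form deformation, control spacing 4 voxels,
ascending an analytic NMI gradient with a linear Parzen window, Gaussian
smoothing of each update as the smoothness regularizer, and a backtracking
line search on the true NMI); nearest-neighbour label propagation through
the pull-back map; per-voxel ranking of the warped atlases by local
normalized cross-correlation (5³ window, border-clipped, constant windows
scored 0); and majority vote among the top-⌈N/2⌉ ranked candidates, ties
resolved by summed similarity then lowest label id. Hemisphere splitting is
geometric (mid-sagittal plane); volumes are voxel count × voxel volume, and
total brain volume is the sum over all labels, ventricles included.

The registration stage is deliberately simplified and pluggable. On
phantoms it recovers translations to <0.05 voxel, self-registers to
near-identity, and reaches per-structure Dice ≥0.85 under moderate unknown
deformations with 3 atlases — but its per-structure *volume* noise floor is
~2–8% on thin structures (sub-half-voxel boundary placement), which is the
documented reason one resolution-robustness acceptance bound (<3% per
structure) stays red. A production registration (block-matching affine +
velocity-field non-rigid) would be dropped in behind the same interfaces.

## Volumetric comparison

PVD = 100·(V_ex − V_in)/((V_ex + V_in)/2), antisymmetric and bounded in
[−200, 200]; both-zero pairs are an error so vanished structures surface.
Bland-Altman summaries use the sample SD (ddof 1) and 1.96·SD limits of
agreement. CNR = (mean GM − mean WM)/SD(background ROI); the ROI is defined
once in a groupwise space (a corner octant by default — a decision, since
real placement is manual) and propagated to each subject through the
inverse of its groupwise affine, with a QA flag if it touches the brain
mask. Group CNR comparisons use one-tailed unpaired t-tests with BH-FDR.

## Statistics

* **w-scores**: per structure, OLS of volume on total brain volume fitted in
  the untreated (reference) group; a subject's w-score is the z-score of its
  residual against the reference residual mean/SD (ddof 1). The source
  prints a "CN" subscript in the numerator mean once; the text defines the
  reference as the untreated group, which is what is implemented.
* **Change rates**: per-subject least-squares slope of volume on age;
  longitudinal rate features are left unnormalized by default.
* **Tests**: paired/unpaired Student t (Welch optional), one-way ANOVA with
  Bonferroni-corrected post hoc pairs within a structure, then BH-FDR across
  structures. Zero-variance degenerate tests return flagged limiting
  p-values (1 or 0) instead of raising, so structure sweeps never abort.
* **Mixed models**: three variants of `volume ~ time × group` — fixed
  effects only; + random intercept; + random intercept and slope with an
  intercept–slope covariance (diagonal optional). Time is centered at the
  first timepoint for conditioning. The mixed variants are REML fits
  (statsmodels MixedLM); the fixed variant is OLS *without* per-subject
  dummies, because subject indicators are collinear with group and
  contradict "individual variation not modelled" (see the design note
  below). AIC = −2·loglik + 2·(fixed + variance + residual parameters);
  successive random-effect structures are compared by a likelihood-ratio
  test against the 50:50 χ²-mixture appropriate at a variance boundary, and
  comparisons that cross the fixed/mixed divide are flagged as mixing ML and
  REML likelihoods (a caveat inherited from the replicated design).
  Relative residuals are 100·(fitted − observed)/observed with conditional
  (BLUP-inclusive) predictions for the mixed forms; on data generated with
  both random terms their mean magnitude orders fixed ≥ intercept ≥
  intercept+slope.

## Classification power

Binary treated-vs-untreated discrimination with a linear SVM at C = 1 and no
tuning (deliberately, to compare data conditions rather than models).
Feature modes: final-timepoint w-scores (*single*), per-structure change
rates (*longitudinal*), or their concatenation (*combined*); plus the same
single-mode analysis on raw and down-sampled ex vivo volumes — five
analyses in total. Within every training fold (and only there): columns are
standardized by training mean/SD (constant columns dropped), PCA keeps the
fewest components reaching 95% cumulative explained variance, and the SVM
is fit on the projected data; test folds are pushed through the frozen
transforms. Stratified 3-fold CV is scored by ROC AUC from decision values
(tied values by rank averaging inside scikit-learn's ROC); learning curves
repeat stratified subsampling without replacement (20 replicates by
default) across sample sizes, reporting mean ± SD training and test
accuracy.

## Pipeline, profiles, determinism

`run_study` chains cohort → rendering + parcellation (three in vivo
timepoints, ex vivo original and spline-down-sampled, each against its
modality-matched atlas set) → CNR → PVD/Bland-Altman + tests → w-scores,
change rates, mixed models (hippocampus, neocortex, ventricles) →
classification, writing CSV/JSON tables and a manifest. Per-stage seeds are
SHA-256 hashes of (master seed, stage name), so stages are independently
reproducible and re-runs are byte-identical. The *fast* profile (default)
coarsens both grids and uses 3 atlases with a 10-iteration non-rigid
refinement, completing a 25-subject study in roughly 15 minutes on one CPU;
*full* keeps the native 150/40 µm grids.

## Numerical choices and degenerate inputs

Sample SDs use ddof 1 throughout. NCC denominators below a relative
tolerance of 1e-10 score 0. Fusion on large grids runs in float32 (exact
voting is unaffected; rank ties between distinct float32 similarities are
broken by atlas order, as documented). PVD with both volumes zero, CNR with
empty/contaminated background, collinear w-score references, and
single-timepoint slope models all raise with named messages rather than
returning NaN. Volume floors (10⁻³ mm³) keep collapsed CSF structures
inside the PVD domain; a structure that falls below one voxel simply
vanishes from the rendered label map, which downstream code treats as an
empty-label row.

## Known limitations

* The simplified registration's per-structure volume noise (~2–8% on thin
  tracts) dominates fine-grained volumetric claims; one acceptance bound is
  red for exactly this reason.
* Phantom geometry is template-consistent ellipsoids; results say nothing
  about atlas-to-subject topology differences or real anatomy.
* The fixed-effect model variant omits the per-subject grouping term (see
  Statistics); AIC comparisons against it inherit the usual ML/REML caveat.
* TBV here includes the ventricles (the brain mask is the union of all
  labels); this is configurable in spirit but is the default everywhere.
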