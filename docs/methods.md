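# Methods

## The biomarker

Net water uptake (NWU) quantifies ischemic edema on non-contrast CT as the
relative hypoattenuation of a region against its mirror region across the
midline:

    NWU_r (%) = (1 − D_ipsi[r] / D_contra[r]) × 100

`D` is the mean attenuation (HU) over the region mask, restricted to the
inclusive 20–50 HU window. The window removes encephalomalacia and CSF
(below 20 HU) and calcification or acute blood (above 50 HU) without any
segmentation step. A region whose valid-voxel set is empty on either side
is *excluded* from the per-scan summaries rather than imputed as 0 — a
fully filtered region carries no density information, and imputation would
dilute the score. Values are not clamped; a denser ipsilateral region
yields a negative NWU.

The written form of the formula is ambiguous about precedence; this package
evaluates `(1 − D_i/D_c) × 100`, the only reading that produces percentages
on the 0–100 scale used throughout the NWU literature.

Two per-scan summaries are computed over the defined regions: the plain
mean of the 10 regional values (sensitive to both infarct extent and
hypodensity depth) and a volume-weighted mean whose weights are the
anatomical region-mask volumes in mm³ on the ipsilateral side. Weighting by
post-filter valid-voxel counts is available as an option but is not the
default, because "region volume" most naturally means the anatomical mask.

**Laterality.** The stroke side is one decision per scan, applied to all 10
regions; per-region side-picking would bias NWU upward under noise (the max
of two noisy mirrored estimates is biased). With `side="auto"` the
hemisphere with the larger candidate average NWU is chosen; ties go to the
left, and an explicit override is available.

## Pipeline

Each scan runs through: load (NIfTI or classic DICOM series, HU-calibrated,
reoriented to RAS) → field-of-view crop (largest above-air connected
component, 2-voxel margin, affine updated so world coordinates are
unchanged) → Gaussian smoothing (default σ = 0.5 × in-plane voxel size —
mild denoising that does not blur region boundaries) → skull stripping
(brain-window candidates restricted to the interior of the filled bone
shell, morphological closing and hole filling, largest component; defaults:
bone ≥ 300 HU, brain window 0–100 HU) → registration to the atlas template
→ resampling onto the atlas grid (linear for intensities with −1024 HU
fill, nearest-neighbor for labels) → regional densities and NWU.

### Registration

Deterministic intensity-based registration: Powell's method over a
three-level pyramid (subsampling factors 4/2/1), minimizing the mean squared
intensity difference over atlas brain-mask sample points, initialized from
intensity centroids with a guarded principal-axes rotation (used only when
the mask moments are clearly anisotropic and the implied rotation is below
45°; near-spherical masks make principal axes ill-conditioned). A 6-dof
rigid stage runs first; a 12-dof affine stage refines it. There are no
random restarts; registration failure sets a `converged` flag in the report
instead of raising, so batch runs continue.

Four numerical details matter and were fixed by phantom diagnostics:

1. **Rim exclusion + intensity clamping.** The metric samples the atlas
   brain mask eroded by 3 voxels, and both images are clamped to
   [−100, 150] HU. The brain/bone rim carries a ~1000 HU step; sampled from
   the inside only, a resampling-blurred subject is best explained by
   *shrinking* the head (a ~2% scale bias), and the unclamped rim dominates
   the cost.
2. **Symmetric metric smoothing.** Both images receive identical extra
   Gaussian smoothing inside the metric (1.0 voxel in the rigid stage,
   0.5 in the affine stage, added in quadrature to the pyramid smoothing).
   With asymmetric blur the optimum wanders by up to half a voxel; with
   symmetric blur the cost is exactly zero at self-alignment.
3. **Robustness to lesions.** Optimization uses trimmed least squares (the
   worst 15% of residuals are ignored) followed by an untrimmed
   refinement restricted to residual inliers (within 3 robust standard
   deviations, floored at 3 HU), re-estimated twice. A focal hypodense
   lesion that the atlas cannot explain must not drag the transform toward
   itself.
4. **Parsimonious dof selection.** The affine result replaces the rigid one
   only when (a) no more than 10% of metric points are residual outliers —
   with a hemispheric hypodensity the 12-dof fit is not identifiable, since
   warping toward the healthy side always "explains" the lesion; (b) the
   rigid fit leaves real misfit (> 0.2 HU²); and (c) the affine cuts a
   robust comparison cost by more than 10%. The comparison cost is evaluated
   on structure-bearing (high-gradient) points under the heavier smoothing,
   over the intersection of both candidates' inlier sets: homogeneous
   interior points say nothing about misfit, lightly smoothed noise rewards
   off-lattice transforms through interpolation averaging, and a
   lesion-chasing transform fits healthy tissue worse and loses.

On the packaged phantoms this recovers a 10°/8 mm rigid perturbation to
≈ 0.2 mm mean brain displacement, anisotropic scalings of 1.1/0.95/1.05 to
within ~1% per axis, and self-registration to ~10⁻⁶ mm.

## The synthetic atlas

The packaged atlas is anatomically schematic by design: exact ground truth
and exact left/right symmetry matter more than realism for validating a
bilateral density comparison. It is built on a grid whose first dimension
is even and centered on the world origin, so the midline plane x = 0 falls
between voxel columns and reflection is an exact voxel permutation.
Geometry (defaults: 96×96×64 voxels at 2 mm isotropic): an ellipsoidal
brain (white matter 33 HU core, gray matter 38 HU cortical ribbon, small
CSF ventricles at 8 HU) inside a 1000 HU bone shell in −1000 HU air. The
four deep regions are separated ellipsoids; M1–M6 are cortical-ribbon
sectors (anterior/middle/posterior × lower/upper).

Three deliberate standoffs protect the density comparison from
partial-volume effects:

* region masks keep ≥ 6 mm clearance from the midline plane, so smoothing
  never mixes hemispheres inside a mask;
* neighboring region masks are separated by ≥ 6 mm buffer gaps;
* cortical sector masks stop ~4.5 mm inside the brain surface. Smoothing
  plus two resampling passes blurs with σ ≈ 1.6 mm; skull HU blended into
  mask voxels would be censored by the 50 HU cut *asymmetrically* between a
  lesioned and an intact hemisphere, biasing regional NWU low by several
  points.

User-supplied atlases (e.g. masks drawn in a standard stereotaxic space)
use the same directory layout (`template.nii.gz`, `regions.nii.gz`,
`brain_mask.nii.gz`, `codes.json`) and are validated for the same
invariants (all 20 codes present, sides strictly lateralized, mirror Dice
≥ 0.95).

## Phantoms

A phantom re-renders the atlas geometry with chosen tissue HU and applies,
in order: lesions, artifacts, additive Gaussian noise (default sd 2 HU,
a typical NCCT noise level), and a pose transform realized by resampling.

An ischemic lesion multiplies the HU of a region *plus a 3 mm dilated halo*
by (1 − w), where w is the water-uptake fraction. The halo reflects that
infarcts extend past parcel boundaries, and it makes the constructed
ipsilateral/contralateral density ratio on the region mask equal *exactly*
1 − w even after mild smoothing: without it, blur mixes unlesioned
neighboring tissue into boundary voxels and dilutes regional NWU by
σ × surface/volume (≈ 5–10% of w) — a phantom artifact, not a pipeline
property. The inter-region buffer gaps guarantee the halo never touches
another region, so unlesioned regions stay at exactly 0. A partial-lesion
mode (`lesion_fraction`) covers only the innermost fraction of a region to
test dilution. Overlapping lesion halos take the strongest reduction rather
than compounding.

Artifacts (calcification 90 HU, hemorrhage 70 HU, encephalomalacia 10 HU)
are inserted as balls at the interior maximum of the region's distance
transform, so they sit strictly inside homogeneous tissue; since all three
HU values fall outside 20–50, the regional density is provably unchanged.

With w ≤ ~0.4 the lesioned tissue stays inside the window; a spec
requesting larger w records a warning in the truth object rather than
failing.

## Cohort simulator

Subjects carry age ~ Normal(69, 14²) truncated to [18, 100], NIHSS ~
discretized Gamma(2, 6.5) clipped to 0–42 (median ≈ 11), tPA ~
Bernoulli(0.44), EVT ~ Bernoulli(0.39), and average NWU ~ Gamma(1.6, 3.5)
(median ≈ 4.5%, tail into the 20s) — scales typical of an acute ischemic
stroke registry. The binary poor-outcome indicator is drawn from a logistic
model whose linear predictor is centered at typical covariate values; the
default coefficients correspond to odds ratios ≈ 1.02/year of age,
1.11/NIHSS point, 0.50 for thrombolysis, 0.74 for thrombectomy and
1.14/NWU point, giving ≈ 55% poor outcomes. An ASPECTS-like 0–10 score is
derived as a noisy decreasing transform of NWU (so both biomarkers carry
the same latent signal, as in real data where both measure the same
infarct). NWU is simulated independently of NIHSS and age — a
simplification that makes coefficient-recovery tests clean but understates
real-world confounding.

## Outcome statistics

All implemented from first principles and cross-checked in the test suite
against independent oracles (enumeration, bootstrap, scipy/statsmodels/
scikit-learn, and a frozen reference from R's pROC for the DeLong test):

* **Logistic regression** by IRLS with step-halving (deviance is
  monotonically non-increasing), Wald standard errors, odds-ratio CIs
  `exp(β ± 1.96 se)`. Separation is reported via `converged=False` (IRLS
  capped at 100 iterations, standard errors above 10³ flagged); an optional
  ridge stabilizer is off by default for transparency.
* **Stratified split**: per-class test counts `round(n_class × fraction)`,
  half-up, with an exact .5 rounding up for the larger class; disjoint,
  exhaustive, seed-reproducible.
* **AUROC** via the rank-sum identity (ties count one half).
* **DeLong** paired comparison from placement-value covariances; when the
  variance of the difference is zero and the AUROCs are equal, z = 0 and
  p = 1 by convention.
* **Fisher exact** two-sided p by the probability-ordering convention
  (documented because conventions differ); the reported odds ratio is the
  sample ratio ad/bc with a Haldane 0.5 correction when a cell is zero.
* **Wilcoxon rank-sum**: exact enumeration for n_x + n_y ≤ 12 without
  ties; otherwise a normal approximation with tie and continuity
  corrections.
* **Cohort description**: binary columns as `n (xx.x%)` (one decimal),
  continuous as median [IQR] with linear (type-7) quartiles; group
  comparisons via the two tests above. No multiple-testing correction is
  applied anywhere; all p-values are raw.

Model comparison fits both covariate-adjusted models on the same stratified
training set, scores the same held-out subjects, and applies the paired
DeLong test to the test-set scores; AUROCs from different test sets are
deliberately unsupported, since the DeLong covariance term requires
pairing.

## Problem sizes and determinism

Default phantom/atlas size is 96×96×64 at 2 mm isotropic — large enough
that every region holds hundreds to thousands of voxels, small enough that
a full pipeline run takes well under two minutes on one CPU. Every
stochastic component (phantom noise, cohort draws, splits) is driven by an
explicit integer seed; registration contains no randomness at all.

## What the phantom tests do and do not show

Phantom recovery demonstrates that the *pipeline* is unbiased and
noise-stable under the constructed conditions: piecewise-constant tissue,
exactly symmetric anatomy, multiplicative whole-region lesions, Gaussian
noise, rigid or mildly affine pose. Real scans add anatomical asymmetry,
partial-volume gradients at every boundary, beam hardening, variable
reconstruction kernels, motion, and lesions that cover arbitrary fractions
of several regions — none of which the phantom emulates. Passing tests
therefore validate the computation, not clinical performance; the cohort
simulator likewise validates the statistics machinery, not any clinical
effect size.

## Known limitations

* Only classic single-frame CT DICOM series are read; enhanced multi-frame
  DICOM is out of scope.
* Registration is affine at most; no deformable refinement, no gantry-tilt
  or motion correction.
* The affine dof is deliberately disabled when more than ~10% of brain
  tissue is hypodense-outlier (extensive infarcts): the rigid solution is
  kept, trading a possible scale mismatch for robustness.
* The synthetic atlas is schematic; results on real scans require real
  atlas masks supplied in the documented layout.
* The cohort simulator draws NWU independently of the clinical covariates.
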