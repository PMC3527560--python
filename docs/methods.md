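# Methods

`ftdmorph` re-implements a structural-MRI analysis for discriminating
dementia groups (controls, FTD, AD, stable and progressive MCI) from three
feature families — hippocampal volumetry (HV), tensor-based morphometry
(TBM) and voxel-based morphometry (VBM) — followed by covariate correction
and a SMOTE-balanced, repeatedly cross-validated regression classifier.
Because no patient scans ship with the package, a synthetic phantom-cohort
generator provides the study conditions; it is first-class, tested code
with exact analytic oracles, not a fixture.

## The phantom and its warps

The template is a spherical head (96 mm domain, default 48³ voxels at
2 mm): a CSF shell, a grey-matter sphere, a white-matter core, and ten
spherical sub-structures covering the seven classification ROIs
(hippocampus L/R, amygdala L/R, posterior temporal lobe, lateral ventricle,
temporal horn, parahippocampal region, anterior cingulate, superior frontal
gyrus).  Each structure has its own mean intensity (CSF 30, GM 100, WM 140,
hippocampus 85, …) plus i.i.d. Gaussian noise (default SD 4).  Giving the
hippocampus an intensity distinct from surrounding GM is a deliberate
idealization: it makes intensity-driven EM refinement highly effective, so
segmentation accuracy on the phantom is an upper bound on what the same
pipeline would achieve on real T1 images, where the hippocampus is
isointense with cortex.

Atrophy is a smooth radial map per structure: inside a core sphere the
anatomy is scaled linearly by `s = f^(1/3)` (`f` the prescribed volume
factor; `f > 1` models ventricular expansion), blending to the identity
over a quintic-smoothstep shell.  The map is analytic, invertible (checked
at construction; over-strong expansion across a narrow shell raises), and
has a closed-form Jacobian determinant — the exact oracle for every TBM
stage.  Structure positions are validated so that warp supports are
pairwise disjoint; the total Jacobian is then the product of per-site
factors times a global head-scale factor `g³` tied to intracranial volume.
Subject label maps are rasterized by evaluating the analytic anatomy at the
warp pre-image of each voxel center, so labels, image and warp are mutually
consistent; `GroundTruth` carries both exact continuous volumes and counted
voxel volumes (they agree to within one voxel shell).

Covariate structure: age is drawn per group (the study's means/SDs), sex
with the study's group-wise proportions; ICV varies log-linearly (5 %
relative SD, a 6 % male/female gap) and scales the whole head; regional
volumes additionally shrink by 0.3 %/year above age 72.  These coefficients
are free parameters of the generator, chosen at realistic magnitudes and
held fixed.  The per-group hippocampus+amygdala volume factors (FTD 0.87,
AD 0.79, SMCI 0.96, PMCI 0.86) equal the study's group hippocampal-volume
ratios relative to controls; factors for the other ROIs are the package's
own choices (frontal and ventricular emphasis in FTD, medial-temporal and
ventricular emphasis in AD) since no quantitative magnitudes are published
for them.

What the generator does *not* emulate: bias fields, motion, multi-scanner
intensity differences, anatomical shape variability beyond the radial
warps, and cortical folding.  Passing tests therefore demonstrate that the
pipeline machinery is correct and recovers planted effects under realistic
noise and covariate confounding — not that it reaches any particular
accuracy on clinical data.

## Registration

The bundled backend is a multiresolution variational registration on a
dense displacement field (fixed-image grid, mm units, fixed → moving
convention; `phi(x) = x + u(x)`).  Each level applies a demons-type
normalized intensity-difference force, caps the per-iteration step (default
0.75 voxel) and re-smooths the field with a Gaussian whose width is
`1 + regularization_weight` mm — smoothing suppresses exactly the
high-bending components, acting as a curvature-type penalty; sweeping the
weight produces monotonically decreasing bending energy.  Three similarity
choices are supported: intensity difference directly; NMI and correlation
ratio by remapping the warped moving intensities to the fixed image's scale
each iteration (conditional-mean matching), after which the difference
force applies.  All three are also implemented as reportable metrics (NMI:
`(H(A)+H(B))/H(A,B)` over 32 equal-width bins).  Registrations never fail
silently: the returned field carries a quality flag (`ok`, `not_converged`
when the final similarity drops by more than 2 % — a tolerance that absorbs
resampling blur — or `folded` on non-positive interior Jacobians).

Jacobian determinants use central finite differences of the total mapping
in physical units, one-sided at the boundary; boundary voxels are excluded
from quality checks because one-sided estimates are biased.

## Multi-atlas segmentation

Per patient: (1) all atlases and the patient are registered to a designated
template; (2) the five atlases with the highest NMI to the patient over the
hippocampus area — the template hippocampus labels dilated by 3 voxels —
are selected, in template space; (3) the patient is registered to each
selected atlas; (4) atlas labels are propagated to the patient grid and
fused into a per-voxel class-probability atlas (vote fractions); (5) EM
tissue classification refines the result, with per-class Gaussian intensity
models and the probabilistic atlas as a fixed spatial prior.  EM is
initialized from prior-weighted image statistics, enforces a variance floor
(1e-6 of the image variance), drops zero-prior classes with a warning, and
stops at a relative log-likelihood change below 1e-6 or 100 iterations; the
log-likelihood is non-decreasing by construction and asserted in tests.
Ties in hard label fusion resolve through the posterior argmax (first class
index on exact ties).  Structure volumes are voxel counts × voxel volume,
in ml.  ICV on the phantom is the volume of all non-background labels
(GM + WM + CSF).

## TBM and VBM

TBM: each subject is mapped to T template images; the Jacobian determinants
of the T fields (template grid) are averaged in log space voxelwise — the
log of the geometric mean — which also symmetrizes contraction/expansion.
Jacobians are not smoothed.  In `truth` field mode the generator's analytic
fields stand in for registration, perturbed with smooth random fields
(default RMS 0.5 mm, 6 mm correlation length) emulating registration error;
`register` mode estimates the fields with the bundled backend.  The
desk-scale default is T = 5 pseudo-templates (T = 3 in the demo study)
rather than 30 — purely a problem-size choice.

VBM: the subject's grey-matter probability (posterior of a flat-prior
4-class EM tissue classification) is pulled to template space along the
template→subject field, then smoothed with a Gaussian of FWHM 4.7 mm
(σ = FWHM/(2√(2 ln 2)) per axis, spacing-aware, zero-padded boundary).
Modulation multiplies the density by the field's Jacobian so values measure
absolute GM volume; modulated and unmodulated variants are separate
features, and double modulation is an error.

Weight images: a held-out reference cohort (synthetic controls vs AD,
generated with its own seed — mirroring the use of a separate dataset)
yields a voxelwise two-sample equal-variance t-map, control minus disease,
with no covariates.  Weights are `w(x) = sign(t)·(1 − p)` where `p < 0.05`,
else 0; an `|t|`-scaled variant sits behind a config switch.  The exact
functional form of `w` from `p` is a design choice of this package (the
thresholded construction is implied by weights having bounded support).
The direction convention is fixed in one place: with control-minus-disease
t-tests, `t > 0` marks disease atrophy for volume-like maps.  TBM,
unmodulated VBM and modulated VBM each get their own weight image.

The ROI feature for a value map v is the weight-averaged atrophic-minus-
expanding difference: `f = [Σ_atrophic |w|v − Σ_expanding |w|v] / Σ_R |w|`,
where the denominator spans both partitions (the per-partition reading is a
config option; the wording that inspired it is ambiguous and both are
computed in tests).  An ROI with no suprathreshold weight yields 0 with an
explicit empty-weight flag; downstream, such a feature standardizes to zero
and carries no information — its classification accuracy sits at chance,
which is the correct behaviour for a null ROI.

## Features and covariate correction

Per subject: left/right/total hippocampal volumes (ml), plus one TBM and
two VBM features per composite ROI.  Every feature is corrected by
ordinary least squares on [1, age, sex(0 = female, 1 = male), ICV] fitted
on healthy reference subjects only (so no disease variance is removed;
default 115 at feature level, 30 image-level in the demo) and standardized
by the reference residual mean/SD — the reference itself therefore comes
out at exactly zero mean and unit SD, and re-correcting is the identity.
Rows with missing covariates are flagged and excluded listwise from
classification.

## Classification

Pairwise evaluation with stratified 90/10 train/test splits repeated 1000
times by default (each repetition re-seeded from a spawned stream of the
master seed).  Within a repetition, training rows only are processed:
SMOTE oversamples the minority to the majority count (synthetic sample
`a + λ(b − a)`, λ ~ U(0,1), b one of a's k = 5 nearest minority
neighbours; originals are returned unchanged), greedy forward stepwise
selection maximizes training CCR (ties to the lowest column index), and a
linear least-squares regression of 0/1 labels is fitted (threshold 0.5;
ridge 1e-8 fallback for singular designs; a logistic variant is a config
switch).  The untouched test rows produce the confusion counts.  The
second-listed (disease/progressive) group is the positive class for
sensitivity/specificity — a labelling convention only, CCR is unaffected.
CCR is reported as mean ± SD over repetitions; SS/SP are pooled over all
test predictions, with per-repetition averages logged alongside.

A caveat this package measures rather than hides: on null data (identically
generated groups) the repeated-split estimate scatters around 0.5 with a
cohort-level SD of roughly `0.4/√n` per group — the same subjects are
re-split, so the estimate concentrates on the *realized* spurious
separability of that one cohort.  Null checks therefore average over
re-generated cohorts and use the re-seed Monte-Carlo band, and calibration
checks against the Gaussian overlap rate Φ(d/2) average over cohorts for
the same reason.

## Pipeline and problem sizes

`run_pipeline` executes simulate → weight images → morphometry maps →
volumetry → feature assembly → covariate correction → classification from
a single YAML-able config; all randomness derives from the master seed via
named spawned streams, so reruns are bit-identical, and the manifest
records the config hash, per-stage timings and output checksums.  Feature
tables are cached by config hash so classification can be re-run without
re-simulation.

In `truth` field mode the morphometry maps carry only the planted effects,
the configured perturbation and intensity noise, so desk-scale pairwise
CCRs saturate near 1 wherever an effect was planted — far above what the
same protocol reaches on clinical data.  The interesting desk-scale
quantities are therefore contrasts (signal ROI vs null ROIs, signal pair vs
null pair), not absolute accuracies.

The demo study ("hippocampal atrophy in FTD only") uses 24 subjects per
group (C, FTD, and a null twin group), T = 3 templates, a 15+15 weight
reference, a 30-subject covariate reference and 150 repetitions — sizes
chosen so a full multi-re-seed run completes on a laptop-class single core
in minutes.  Acceptance-style checks run the demo at five re-seeds and ask
that the hippocampus+amygdala ROI win the single-ROI comparison in ≥ 80 %
of re-seeds, that C-vs-FTD multi-ROI TBM CCR exceed 0.75, and that the
null pair stay within the re-seed Monte-Carlo band of 0.5.

## Numerical choices and known limitations

* Coordinates: 0-based indices, `world = origin + index·spacing`, no
  rotations; NIfTI affines are diagonal.
* Interpolation: trilinear for intensities/probabilities, nearest for
  labels; out-of-field samples take a configurable background value.
* EM variance floor 1e-6·var(image); registration step cap 0.75 voxel;
  stepwise ties to the lowest index; SMOTE k capped at minority size − 1.
* The registration backend is intentionally basic: diffusion-style
  regularization rather than an explicit B-spline bending-energy
  optimizer, and sub-voxel warps (boundary shifts ≲ 0.5 voxel) are at its
  recovery limit — which is why TBM testing leans on the analytic field
  mode, with registration validated separately on translations and
  super-voxel warps.
* Laterality is modelled by separate left/right labels (atlas-style), not
  a midline split; only the hippocampus/amygdala are lateralized in the
  phantom.
* Multi-class classification, ROC analysis, asymmetry features and scanner
  harmonization are out of scope.
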