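# Methods

## The reduction

Whole-brain white-matter (WM) myelin water fraction (MWF) maps carry a
voxel-level signature of demyelination: visible lesions have low MWF,
"dirty" WM sits between lesions and normal-appearing white matter (NAWM),
and NAWM itself carries most of the volume at high MWF.  Instead of
delineating lesions, `mwfmix` reduces each subject's pooled WM MWF
distribution to a parametric summary.  The per-subject model is a
two-component gamma mixture

    p(x) = lam * Gamma(x; a1, b1) + (1 - lam) * Gamma(x; a2, b2),  x > 0,

with shapes `a`, scales `b`, and mixing ratio `lam` attached to the
low-mode component.  The subject is summarized by three numbers:

* `m1 = (a1 - 1) b1` — mode of the low-MWF component (lesional / dirty WM);
* `m2 = (a2 - 1) b2` — mode of the high-MWF component (NAWM);
* `lam` — the proportion of abnormal-looking WM.

Modes are truncated at zero when a fitted shape drops below 1 (the density
is then monotone); `summarize_fit` flags this boundary case with a warning.

## Estimation

The single gamma is fitted by maximum likelihood: the shape solves
`log k − ψ(k) = log(mean) − mean(log)` by safeguarded Newton iterations
from the standard closed-form approximation, and `scale = mean / k`.

The mixture is fitted by expectation maximization on the raw voxel values
(no histogram binning; results are invariant to value order up to float
rounding).  The E-step computes low-component responsibilities in log
space; the M-step sets `lam` to the mean responsibility and solves each
component's *weighted* gamma likelihood with the same Newton solver.
Initialization is deterministic and scale-free: split the values at their
median, moment-match a gamma to each half, start at `lam = 0.5`; if a half
is degenerate, split at the 20th percentile instead.  EM stops when the
relative log-likelihood change falls below `tol = 1e-8` or after
`max_iter = 2000` iterations (non-convergence is flagged, not raised).  A
component whose responsibility mass falls below 10 effective observations
raises a collapse error directing the caller to the single-gamma model.

**Ridge refinement.**  For realistic MWF mixtures the two components
overlap strongly and the likelihood has a very flat ridge along which
`lam` and `m1` trade off; EM's per-iteration log-likelihood gain shrinks
below any practical tolerance while the parameters are still drifting
(reaching the ridge bottom takes ~10^4 iterations).  After the EM loop the
implementation therefore refines the same log-likelihood directly with a
Nelder–Mead pass in unconstrained coordinates (logit mixing ratio, log
shapes/scales), accepting the result only when it improves the
log-likelihood — the EM path itself stays monotone, which the tests
verify.  The refined optimum agrees with an independent direct likelihood
search to < 0.01 in `lam` on 100,000-value samples.

**Identifiability caveat.**  With components of shapes 2 and 5 at modes
0.06/0.17 the exact MLE of `lam` has sampling SD ≈ 0.030 even at
n = 100,000 (measured by repeated-seed simulation with an independent
direct optimizer); `m1` has SD ≈ 0.0043 and `m2` ≈ 0.0016.  Recovery
tests therefore use 2-SD bands around the generating values; tighter bands
would fail for a typical seed *for the exact MLE itself*.

## Model choice

A penalized likelihood ratio statistic compares the fits:

    T = 2 * [ (ll_mixture + log(4 lam (1 - lam))) − ll_single ].

The penalty is zero at `lam = 0.5` and −∞ at the `lam ∈ {0, 1}` boundary
where the classical test is irregular; it can only diminish the evidence
for the mixture.  Because no convenient reference distribution holds at
the boundary, the null is calibrated by parametric bootstrap: draw B
samples (B = 199 by default; at least 19 required) of the observed size
from the fitted single gamma, refit both models on each, and report the
add-one exceedance proportion `p = (1 + #{T_b ≥ T}) / (B + 1)`; the
mixture is chosen iff `p < 0.05`.  The p-value floor is `1/(B+1)`, so a
decisive choice at the 0.05 level needs B ≥ 39.  Measured type-I error at
n = 300, B = 99 is at or below nominal, and clearly bimodal samples select
the mixture with p at the floor.

## Masks, ROIs and overlap

The classical route builds a lesion mask from a FLAIR-like intensity
volume: candidates are the third segmentation class (CSF + lesions)
intersected with WM, thresholded at the 30th percentile of the robust
intensity range — implemented as `p2 + 0.30 (p98 − p2)` over the nonzero
image with linearly interpolated percentiles, i.e. a point three-tenths of
the way into the robust range rather than a re-ranked percentile.  NAWM is
the WM complement of the lesion mask; the two always partition WM.

The mask-free route thresholds the MWF map at the fitted modes:
`ROI[m1]` = WM voxels strictly below `m1`, `ROI[m2]` = strictly above
`m2` (strict inequalities; voxels exactly at a mode are measure-zero for
continuous data).  Correspondence is quantified per subject by the Dice
coefficient `2|A∩B| / (|A|+|B|)` and across subjects by a two-sided Welch
two-sample t-test on the Dice lists, treating the two lists as independent
samples even though they are paired within subjects (the paired
alternative would be more powerful; the independent-samples form is kept
for comparability with standard practice).  On synthetic cohorts the
lesion mask overlaps `ROI[m1]` far more than `ROI[m2]` and vice versa for
NAWM, with `Dice(NAWM, ROI[m2]) > Dice(lesion, ROI[m1])` — the small
lesion volume bounds the lesion Dice numerator.

## Group models

Cortical thickness (mm) is regressed on per-subject features.  Two
predictor families are compared, never mixed in one model: the mixture
reduction {m1, m2, lam} and the mask summaries {mean lesion MWF, mean NAWM
MWF}, each together with age, gender (0/1 indicator), disease duration and
treatment duration.  For each family, all 2^p subsets (intercept-only
included) are scored by k-fold cross-validated MSE (k = 10); subjects are
shuffled once with the run seed and the same folds are reused for every
subset so the errors are comparable.  The minimum-CV-MSE subset wins, ties
broken by fewer predictors then lexicographic order, and is refitted on
all data; families are compared by adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).
Note that minimum-CV selection retains a spurious predictor with
non-vanishing probability (≈ 0.15 per candidate, akin to AIC), so
exact-subset recovery plateaus around 60% with four candidates even under
strong signal; the tests assert the (much more reliable) inclusion of the
active predictor.

Relative importance uses the LMG decomposition: a predictor's share is the
average R² gain over all orders in which it can enter the model, computed
over all subsets with factorial weights (≤ 10 predictors).  Shares are
nonnegative and sum exactly to the full model's R².

Coefficients are interpreted as the all-else-equal predictor change
associated with a fixed thickness change: `Δpredictor = Δthickness /
|coefficient|`, with Δthickness = 0.05 mm by default; values are kept at
full precision and rounded to two significant figures only for
presentation.

## Synthetic data

**Volumes.**  The WM mask is an axis-aligned ellipsoid filling
`wm_fraction` (default 0.45, ≈ 59,000 voxels on the default 64×64×32
grid — desk scale yet enough for a stable EM fit).  Lesions are
non-overlapping spheres (radii uniform in 3–5 voxels by default, largest
placed first by rejection sampling inside the eroded ellipsoid; an
unplaceable load is an error), each wrapped in a 1.5-voxel dirty-WM rim.
Lesion and rim voxels together receive one iid sample from the low-MWF
component, with the rim taking values from the sample's upper portion —
`dirty_overlap` interpolates between a random assignment (0) and strictly
the top order statistics (1; default 0.5).  The remaining WM draws from
the high-MWF component, and values are clipped to [0, 1] since MWF is a
signal fraction.  This construction makes the pooled WM histogram *exactly*
the generating mixture (KS distance ≈ 0.003 at 59k voxels): an earlier
variant that truncated the rim draws instead distorted the pooled density
by ~2% of mass, which the weakly identified MLE amplified into `lam`
errors of 0.1–0.3.  The default lesion count (20) makes the expected
lesion+rim volume ≈ 25% of WM, matching the default mixing ratio.

**FLAIR-like intensities.**  WM at 100, lesions raised by `lesion_gain`
(default 20), a synthetic CSF shell (two-voxel dilation of WM) at 30,
Gaussian noise (default SD 5) on brain voxels, background zero.  The
"class 3" map emulates an intensity-driven segmentation whose third class
mixes CSF and lesions: the CSF shell united with robust hyperintensity
outliers (brain voxels above the WM median + 2×1.4826·MAD).  It is derived
from the noisy intensities rather than copied from the ground truth, so
recovery degrades to chance when `lesion_gain = 0` and is exact in the
noise-free separable case — the behavior a segmentation-based mask rule
actually has.

**Cohorts.**  Subject tables draw predictors from configurable
distributions and generate thickness as `intercept + Σ coef·x + N(0, σ)`.
The two group presets emulate a relapsing-stage cohort (n = 134; age
40.3 ± 9.7 y, 67% female, DD 7.7 ± 7.3 y, DMT 4.2 ± 4.1 y; thickness
driven by m1 (+1.56), lam (−0.30) and age (−0.0031 mm/y) around 2.46 mm,
noise SD 0.11) and a progressive-stage cohort (n = 23; age 57.4 ± 7.8 y,
DD 21.7 ± 11.0 y, DMT 10.6 ± 6.1 y; thickness driven by m2 alone, +4.72,
around 2.27 mm, noise SD 0.10, with lower modes and higher mixing ratio).
Mixture-parameter spreads (m1 0.06 ± 0.01, m2 0.17 ± 0.015 truncated to
disjoint ranges, lam 0.25 ± 0.08 / 0.45 ± 0.12) are chosen to give
adjusted R² in the published ballpark (≈ 0.1–0.2 relapsing, ≈ 0.4–0.7
progressive) rather than calibrated to any dataset.  Mask-mean columns are
noisy linear surrogates of the modes (a gamma with shape 2 and mode m has
mean 2m; shape 5, mean 1.25m; surrogate noise SD 0.012), encoding the
surrogate relationship between the mask summaries and the mixture
parameters.

**What the generators do not emulate:** T2-decay signal formation, coil
sensitivities, B0/B1 inhomogeneity, registration error between contrasts,
partial-volume mixing at tissue boundaries, spatial autocorrelation of
MWF noise within tissue classes, non-ellipsoidal anatomy, and
periventricular lesion topography.  Passing tests therefore demonstrate
the statistical machinery is correct under the model's own assumptions,
not that the assumptions hold on scanner data.

## Pipeline and problem sizes

`run_subject` fits both models on (a subsample of) the pooled WM values —
20,000 voxels by default, statistically ample given the MLE SDs above —
runs the bootstrap selection, and derives the summary, ROIs, Dice values
and mask means.  Subjects whose selection keeps the single gamma stay in
the cohort table with null mixture fields.  `run_study` adds an image arm
(simulated or ingested volumes → fits → per-group Dice comparisons; the
per-subject mixing ratio is capped at ≈ 0.3 so the implied lesion load
still packs into the WM ellipsoid, with automatic back-off when it does
not) and a cohort arm (group tables → Welch comparisons → both
predictor-family selections → LMG of the winning mixture model).  The two
arms are statistically independent by design; regression analyses run on
cohort-level tables at the published group sizes rather than on the small
image arm.  Every stage writes its own artifact; failures are recorded in
the manifest and remaining stages still run.  Fixed seeds give
bit-identical bundles.

Default study sizes (10 + 10 image subjects, bootstrap B = 39, 10-fold
CV) run in a few minutes on one core; the test suite uses 20-subject Dice
cohorts at the default volume spec, a 96×96×48 grid (≈ 200,000 WM voxels)
for the mixing-ratio recovery check, and 100 × B = 99 replicates for the
type-I calibration.

## Known limitations

* `lam` is weakly identified when the components overlap as strongly as
  the defaults; report it with its modes, not alone, and prefer larger WM
  voxel counts.
* The bootstrap selection is expensive (B + 1 mixture fits per subject);
  B = 39 is the practical default at volume scale, B = 199 for final
  analyses.
* The Welch test on Dice lists ignores within-subject pairing.
* Minimum-CV-MSE subset selection over-selects mildly; interpret the
  selected set as "contains the active predictors" rather than exact.
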