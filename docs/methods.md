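# Methods

This note documents the models, conventions and design choices behind
`mstconnect`: what each stage computes, which parameters matter, what the
synthetic cohort generator does and does not emulate, and where genuinely
open design questions were resolved by a documented choice.

## Framewise displacement and censoring

FD uses the RMS formulation: per volume, the relative rigid transform
between consecutive volumes, `M = T_t · T_{t−1}⁻¹ − I`, is summarised as
`FD = sqrt((R²/5)·tr(AᵀA) + bᵀb)` — the root-mean-square displacement of
points filling a sphere of radius `R` centred at the rotation centre.
Conventions (configurable, defaults stated):

- rotation order `R = R_z·R_y·R_x`, rotations in radians, applied about
  the coordinate origin; head radius `R = 80 mm`. The source convention
  for rigid transforms is not uniquely determined by the phrase "RMS
  displacement", so both the radius and the centre are parameters.
- motion-parameter file dialect: translations (mm) first, then rotations
  (radians).
- FD is exactly invariant to a common translation offset only when the
  rotations do not change between volumes; the unit test asserts the
  invariance in that regime.

Censoring: volumes with `FD > 0.2 mm` (strict inequality) each receive a
unit indicator regressor ("spike regression"). Censored volumes are
*retained* in the series — their residuals are driven to ~0 by the
indicator columns — rather than deleted, so all subjects' correlations
use a common column set; a deletion mode exists for sensitivity checks.
Subjects are excluded when retained data is strictly below 4 minutes
(`n_retained · TR < 240 s`; at TR = 1.6 s the boundary is exactly 150
volumes, which is kept). Mean FD used as a covariate is computed over
all analyzable volumes, pre-censoring (a flag switches to post-censoring).

## Nuisance model and filtering

The 36-parameter design stacks Friston's 24 motion regressors (6
parameters, their one-volume lags, and the squares of both) with 12
tissue regressors (GM/WM/CSF mean courses, first differences, squares of
both). Lags and differences at volume 0 are set to 0. An intercept is
always appended; rank deficiency is handled by an SVD least-squares
solver, and residuals are verified orthogonal to every design column.

Pipeline order: linear detrend → nuisance regression (36P + spikes) →
band-pass 0.01–0.08 Hz for the connectome branch only. ALFF is computed
on the unfiltered residuals because the band selection is ALFF's own.
The band-pass is a zero-phase (forward-backward) Butterworth of order 4;
at the 0.16 Hz double-band-edge the squared response attenuates by more
than 99%. Pass-band checks exclude ~30 edge samples where the
forward-backward transient lives.

## ALFF

ALFF is the mean of the square-rooted power spectrum over 0.01–0.08 Hz,
DC excluded, bins included when `low ≤ f ≤ high`. The spectrum scale is
the one-sided amplitude spectrum `2/T·|FFT|`; any fixed scale is
equivalent because group analysis consumes only the z-scored map
(z-scoring uses the sample sd, ddof = 1, over all units in the supplied
mask). Spectral leakage from off-bin out-of-band tones is a property of
the rectangular window, not an error; the tests pin it against a direct
DFT oracle. Gaussian smoothing uses `σ = FWHM/(2√(2 ln 2))` per axis with
reflective boundaries (flat maps stay flat; the global mean is
preserved). Spherical small-volume masks include a voxel when its centre
is within the radius of any sphere centre; a packaged preset holds the
five discriminative-peak coordinates used for small-volume correction.

## MST connectome

Connectivity is the Pearson correlation of the (filtered, residual) ROI
time series, after removing a configurable exclusion set (`occipital8` /
`occipital16` presets map to the last 8/16 labels of the synthetic
parcellation, standing in for occipital regions outside a limited field
of view; with 246 ROIs the `occipital8` preset leaves 238 nodes and
28 203 unique edges).

The backbone is the *maximum*-weight spanning tree: negative correlations
are zeroed, only strictly positive weights are candidate edges (a
disconnected positive subgraph is an error, never silently patched), and
Kruskal's algorithm with union-find runs over edges sorted by descending
weight, ties broken by node index for bit-reproducibility. Metric
normalisations, each pinned to the extremal topology that attains 1:

- leaf fraction: `(#degree-1)/(N−1)` (star = 1);
- diameter: `edges of the longest path/(N−1)` (path = 1);
- average eccentricity: mean of per-node maximal hop counts, `/(N−1)`;
- betweenness: interior-node pair counting via subtree sizes, normalised
  by `(N−1)(N−2)/2` (star centre = 1, leaves = 0). Whether the original
  analysis software counted path endpoints is unverifiable; interior-node
  counting (standard betweenness) is used, which matters only for
  cross-study numeric comparability, not correctness.
- average strength is the unnormalised mean of included original weights.

## Statistics

All permutation tests are two-sided and seeded, with the add-one
estimator `p = (1 + #{|stat*| ≥ |stat|})/(n_perm + 1)` (so `p ≥
1/(n_perm+1)`; default `n_perm = 10 000`). Quantiles (median, IQR,
quartiles for the 3·IQR outlier rule) use linear interpolation between
order statistics — the outlier set depends on this convention, so it is
fixed and tested. The 3·IQR screen is single-pass; values equal to a
quartile are never removed.

The omnibus group × metric test z-standardises each metric column, then
computes repeated-measures F-type statistics (between-subject group
factor, within-subject metric factor). Group and interaction nulls come
from permuting subject group labels (whole subjects, preserving
within-subject correlation); the metric null shuffles metric labels
within subjects. Note a structural consequence: after per-metric
standardisation the metric main effect is degenerate — observed F ≈ 0
and p ≈ 1 by construction — so the informative outputs are the group and
interaction p-values. The original omnibus statistic was described only
in an unavailable supplement; this reconstruction is the package's own.

The motion-sensitivity suite screens residual motion against connectome
outcomes with Kendall's tau-b: per-edge tau against mean FD with BH-FDR
(reported as % significant edges plus the full tau distribution and its
mean), per-global-metric tau with uncorrected p (matching how such
screens are conventionally reported; a flag adds FDR), and per-node tau
for degree and betweenness with BH-FDR. Edges with zero variance yield
NaN ("undefined") entries, reported rather than raised. A significant
leaf-fraction association flags that metric as motion-confounded and the
pipeline then excludes it from group testing — a pre-registered gate.
The vectorised edge-wise tau assumes effectively tie-free continuous
inputs for its normal-approximation p (the scalar route uses exact
enumeration for n ≤ 10 without ties); the two routes are cross-checked
in the tests.

The cluster test on voxel maps residualises covariates of no interest
first (Freedman–Lane), computes pooled-variance two-sample t per voxel,
forms 26-connected clusters above the two-sided cluster-defining
threshold (default p < 0.001) and compares each cluster's *mass* (sum of
suprathreshold |t|) against the permutation null of the maximum cluster
mass (FWE control). Variance smoothing (pseudo-t) used by some
neuroimaging packages is deliberately not reproduced; cluster mass is
the documented statistic.

Minimal detectable effect: the smallest Cohen's d whose two-sided
two-sample t-test power reaches the target, via the noncentral-t
distribution (df = n1+n2−2, noncentrality `d·√(n1·n2/(n1+n2))`),
bisected to 1e-4. For n = 24 vs 22 at α = 0.05 and 80% power this gives
d = 0.8455.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Motion.** Each rigid-body parameter is an AR(1) process (ρ = 0.98)
with innovation sd proportional to the group's motion scale
(0.03 mm/translation, 3.75e-4 rad/rotation at scale 1 — at the 80 mm
head radius both contribute ≈0.03 mm frame-to-frame, putting a scale-1
subject's median FD near 0.06 mm, comfortably under the 0.2 mm censor
threshold). With probability `spike_rate` (default 0.02) per volume a
5–10× innovation jump hits one translation axis. Group A (responders)
uses scale 1.0, group B 1.5: the direction mirrors the emulated finding
(responders move less), but the magnitude is illustrative — no empirical
motion effect size is available to calibrate against.

**ROI signals.** A unit-variance latent source at the planted tree's
root propagates along edges with attenuation `a` (default 0.9):
`z_child = a·z_parent + √(1−a²)·ε`; observation adds white noise of sd
`σ` (default 0.5). Population correlation at tree distance `d` is
`a^d/(1+σ²)` (adjacent pairs ≈ 0.72 at the defaults), strictly
decreasing in `d`, so the planted tree is the unique maximum-weight
spanning tree of the population correlation matrix — the property that
makes tree recovery a well-posed oracle. Latent sources and propagation
innovations are unit-variance AR(1) processes (ρ = 0.85), concentrating
power at low frequencies the way BOLD fluctuations do; the correlation
formula is spectrum-independent, but this choice means the 0.01–0.08 Hz
band-pass downstream preserves rather than erases the planted structure.
Group A's tree plants three hub nodes (preferential attachment with
probability 0.5); group B's tree is random-attachment. An FD-locked
artifact (gain 0.5, per-ROI loadings ~N(1, 0.2²)) is added so censoring
and nuisance regression have real work to do.

**Clinical scores.** Baseline CAPS ~ N(70.33, 15.3²) truncated at 0.
Fractional reductions come from truncated normals: responders
N(0.55, 0.15²) on [0.30, 0.95], non-responders N(0.10, 0.12²) on
[−0.25, 0.29]. The truncation boundaries coincide with the ≥30%
classification rule, so generated group labels and downstream
classification agree exactly. Per-subject randomness derives from
`SeedSequence(seed).spawn(subject index)`: identical specs reproduce
cohorts bit-for-bit, and subjects are mutually independent.

**What is not emulated** — and hence what passing tests do not show
about real data: no scanner physics or k-space artifacts, no voxelwise
motion interactions (the FD-locked artifact is a rank-one caricature),
no physiological (cardiac/respiratory) noise, no hemodynamic response
shape, no spatial autocorrelation between ROIs beyond the planted tree,
and Gaussian marginals throughout. Recovery results validate the
*analysis chain's* correctness and calibration, not its sensitivity on
real BOLD data.

## Problem sizes used by the validation suites

Chosen as the package's own trade-off between Monte-Carlo resolution and
a single-CPU run: planted-hub recovery uses 50 replicate cohorts of
24 + 22 subjects with 60 ROIs × 150 volumes and 500-permutation tests
(plus 50 matched null cohorts); the cluster-FWE calibration uses 200–300
null datasets of 10 + 10 subjects on 8×8×8 grids with 500 permutations
and CDT p = 0.005 (at p = 0.001 on so small a grid most null datasets
form no cluster at all, making the rate estimate needlessly coarse); the
two-group calibration uses 300–400 null draws at 200 permutations; the
end-to-end demo runs the full 46 × 246 × 320 configuration with 10 000
permutations, twice, to assert bit-identical outputs.

## Known limitations

- The FD rotation centre and the exact eccentricity/BC normalisations of
  the original analysis software are unverifiable; all are configurable
  or documented, and affect cross-study numeric comparability only.
- The omnibus statistic is a reconstruction (see above).
- The whole-brain voxel mask of the emulated analysis is not
  reconstructible; voxel-level operations accept a user-supplied
  inclusion mask instead.
- ALFF group differences can arise in the synthetic cohort through the
  tissue-regression channel (the GM mean correlates more with well-hubbed
  ROIs, so regressing it removes unequal variance across topologies) even
  though the generator plants no direct ALFF effect; this is a property
  of global-signal-style regression, visible in the demo output.
- Because the planted trees differ globally between groups, global MST
  metrics also differ in the demo cohort; the generator plants nodal
  structure, it does not enforce a global-metric null.
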