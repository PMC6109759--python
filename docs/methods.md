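# Methods

This note documents the models, parameter choices and numerical decisions
behind `fceq`, and what the synthetic experiments do and do not establish.

## Signal model of the synthetic cohort

Each subject's series is generated as

```
y(v,t) = baseline
       + Σ_networks [ Σ_nodes  m_node(v) · g · h_node ⊛ s(t)     (task response)
                      + m_net(v) · a · φ(t) ]                    (spontaneous FC)
       + d(t) + ε(v,t)
```

* `s(t)` — the condition's zero-one stimulus boxcar; `h_node` the HRF,
  optionally delayed per node; `g` the signed coupling gain (+1.0 visual,
  −0.6 DMN by default: negative BOLD is the weaker signal).
* `φ(t)` — the network's spontaneous fluctuation: seeded white Gaussian
  noise low-pass filtered at 0.1 Hz (4th-order Butterworth, the band FC
  fluctuations live in), variance-normalized, scaled by `a` (default 1.0),
  and redrawn (up to 100 times) until it correlates with every task
  regressor at |r| < 0.1. Resampling rather than orthogonalization
  preserves the fluctuation's spectrum.
* `d(t)` — scanner drift, a slow cosine (period 128 s, amplitude 1.0,
  seeded phase); `ε` — white Gaussian noise, SD 0.5.
* Geometry is a desk-scale abstract volume (20 × 20 × 10 voxels of
  3 × 3 × 5.5 mm), not an anatomical template: the inference procedure is
  geometry-agnostic. Network templates are smooth spherical nodes
  normalized to peak weight 1; distinct networks must have near-disjoint
  supports (Dice < 0.05), which is what spatial ICA assumes.

Event timing reproduces the study design statistics: inter-onset intervals
from a truncated exponential on [4, 18] s calibrated to mean 6.2 s exactly,
durations from a truncated log-normal (σ = 0.5 log-s) on [0.5, 3.5] s
calibrated to mean 1.2 s; both solvers use deterministic root finding. A
motor event follows each visual offset. Each subject draws independent
timing (seed = master seed + subject index) — the permutation null requires
unique schedules.

## Why the DMN's deactivation is a distinct source

Spatial ICA can only separate processes whose spatial profiles are linearly
independent. If the DMN's negative BOLD response rode on exactly the same
weight map as its spontaneous fluctuation, the two would fuse into a single
component algebraically (one map, summed time-courses) and *any* pipeline
would find the DMN time-course task-laden — simulation at the default
conditions confirms this, and the equivalence test then flags the DMN as
altered, which contradicts the phenomenon being modeled. Conversely, if the
deactivation were purely nodal with the network map equal to the sum of its
node maps, the network would fragment into per-node components, each again
task-laden.

The default scene therefore models deactivation and connectivity as
overlapping but distinct sources, which is also the standing physiological
account: negative BOLD in the default mode has node-specific hemodynamics.
Concretely, the DMN's task response is concentrated on sharper node cores
(node radius × 0.6) with staggered per-node response delays (−2, 0, +2 s),
while its spontaneous fluctuation spans the full three-node map coherently.
The visual network keeps one map for both processes — there, task and
connectivity genuinely fuse, which is exactly the asymmetry the study
design probes. Both knobs are configuration (`dmn_task_core_scale`,
`dmn_node_delays`); setting them to 1 and (0,0,0) restores the
single-source variant for sensitivity analyses.

## Preprocessing

Fixed order: high-pass → smooth → intensity-normalize; any stage can be
skipped.

* **High-pass (default 0.01 Hz).** A Gaussian-weighted running-line
  detrend: at each time point a weighted linear fit (truncated at ±4σ,
  border-renormalized) is subtracted and the voxel's temporal mean restored
  exactly. The kernel width is calibrated so the filter passes half the
  amplitude at the nominal cutoff, σ = √(2 ln 2)/(2π·f_c·TR) ≈ 18.7
  volumes at 0.01 Hz/TR 1 s. (The often-quoted σ = 1/(2 f_c TR) puts the
  half-amplitude point near f_c/3 and barely attenuates below the cutoff;
  it fails the attenuation contract this module is tested against.) A
  DCT-basis regression filter (`method="dct"`) is the sharper alternative.
* **Smoothing (default FWHM 5 mm).** Per-axis σ = FWHM/(2√(2 ln 2)) divided
  by voxel size; borders renormalized by the smoothed all-ones volume, so
  constants pass through exactly and no mass leaks out of the volume.
* **Intensity normalization (default median 10⁴).** One global scale
  factor. The median is taken over all voxels by default because synthetic
  volumes have no anatomical background; a mask argument restricts it.

## GLM

Canonical HRF: double-gamma (response gamma shape 6/scale 1, undershoot
shape 16, ratio 1/6; peak ≈ 5 s), sampled on a 0.01 s grid for peak-1
scaling; the single-gamma Boynton form (shape 3, τ = 1.25 s) is selectable.
Regressors are built on a 0.1 s grid, convolved, scaled by the grid step
(response amplitude proportional to event duration for brief events) and
read at volume times. Columns are not demeaned; an explicit `constant`
column carries the intercept and is excluded from "predictors of interest".

Fitting is plain voxelwise OLS — no prewhitening, since the synthetic noise
is white by default; this is a known limitation against real fMRI noise.
t → z conversion goes through the t tail probability and the normal
quantile, with dof = T − p; degenerate statistics saturate at |z| = 40.
Residualization stores `residual + temporal mean`; residuals are orthogonal
to the design to ~10⁻¹⁰ relative, and the operation is idempotent.

The group map is a voxelwise one-sample t across subject betas (dof n − 1),
not a mixed-effects model: group maps are illustrative here, the inference
path is subject-wise similarity. Zero-variance voxels cap at ±40.

## Spatial ICA

Voxels are samples, time points variables. After per-voxel demeaning and
removal of the mean volume, the T × T Gram matrix gives the PCA
eigenspectrum; the data are whitened onto the top k eigenvectors and
FastICA (logcosh contrast, tolerance 10⁻⁴, max 1000 iterations) unmixes
spatially. Five restarts from seeded initializations are the library
default (the study pipeline uses 3; the forced-20-component diagnostic uses
10 restarts with tolerance 10⁻², since the fixed point over mostly-noise
dimensions is slow to settle); among converged restarts the run with the
largest total logcosh negentropy wins, and if none converges a
`ConvergenceError` carrying the iteration count is raised. Maps are
z-scored (the spatial mean is zero by construction) with the scale folded
into the time-courses, so map × time-course products — and hence the
reconstruction of the PCA-reduced data — are preserved exactly. Components
are ordered by explained variance.

Model order: Minka's Laplace evidence over the eigenspectrum, argmax
clamped to [2, T − 5]. On the default synthetic subject the evidence picks
2–3 — the visual and DMN fluctuations dominate; the weak nodal deactivation
sources sit near the Marchenko–Pastur bulk of the smoothed-noise spectrum
and are legitimately not counted. The study config scans candidates up to
60 (the peak at desk scale is far below; the clamp ceiling still applies).

Matching and sign: a network's component is the one maximizing |spatial
Pcc| with its reference map (ties to the lower index); its sign is fixed so
that correlation is nonnegative (map and time-course flip together,
preserving the product; an exactly-zero correlation keeps +1). In
simulation mode the references are the ground-truth maps; on real data they
would be user-supplied template masks. Downstream similarity records are
invariant to ICA's component order and sign by construction (tested).

Group mode concatenates subjects along time after per-voxel demeaning and
variance normalization, records subject boundaries, and slices per-subject
time-courses back out; spatial metrics are then group-level and shared
across subjects. Subject-wise ICA is the default inference path —
group-level spatial comparisons are degenerate under the paired test
(zero between-subject variance) and in the modeled study they were the
normalization-sensitive arm.

## Similarity and the equivalence test

Temporal Pcc compares matched time-courses; spatial Pcc compares matched z
maps over the full analysis mask, unthresholded; Dice binarizes at
z ≥ 3 (positive tail only, since matched components are sign-fixed toward
their reference) and is recorded as missing-with-reason when both
thresholded maps are empty.

The null arm re-residualizes each subject against a donor's timing. The
permutation is a uniform random derangement — fixed points would remove the
subject's *own* task and contaminate the null — sampled by seeded
rejection; rounds are distinct whenever the subject count permits. Default
is one round (one permuted re-analysis), configurable upward, with
per-subject null values averaged across rounds before pairing. The paired
t-test uses per-subject (observed − null mean) differences, dof = pairs − 1,
one-sided against similarity reduction (the two-sided p is reported
alongside); verdict `altered` requires p < α (default 0.05) *and* observed
mean below null mean. Zero-variance differences cap |t| at 40. No
multiple-testing correction is applied across the 2 networks × 3 metrics;
all six p-values are reported side by side.

## Problem sizes and determinism

The shipped experiments run at the study's scaled-down scene: 8-subject
cohorts (the real study had 30), 20 × 20 × 10 voxels, 360 volumes, with 20
seeded replicates for the dissociation and specificity rates and 10⁴
white-noise voxels for z calibration. Every random draw — schedules,
fluctuations, noise, ICA initialization, permutations — flows from explicit
seeds, and `run_study` reproduces its output tables byte-identically under
a fixed config; a config hash and all seeds are stamped into every table
header.

## What passing tests do and do not show

The generator omits physiological noise (cardiac/respiratory), motion,
slice-timing effects, temporal autocorrelation (an AR(1) structure would
require prewhitening the GLM lacks), scanner artifacts, and anatomical
geometry. Passing the synthetic checks therefore shows the *inference
machinery* is correct and calibrated — that residualization removes exactly
the modeled variance, that the permutation null has the intended
distribution, that the paired test controls type-I error, and that the
dissociation emerges whenever deactivation and connectivity are distinct
sources. It does not by itself establish how often real DMN deactivation is
separable in scanner data; on real data the verdicts also inherit the
choices of reference maps and model order.

## Known limitations

* OLS without prewhitening; white-noise synthesis by default.
* Component z-scoring by map moments rather than a mixture-model fit; the
  z ≥ 3 threshold semantics are approximate.
* The Laplace order estimate is honest but conservative at low SNR; forcing
  `n_components` is the recommended sensitivity analysis.
* Dice at z ≥ 3 on z-scored maps is quantized on small supports, making it
  the noisiest of the three metrics.
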