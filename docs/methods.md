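# Methods

This package implements a multimodal stress-and-ergonomics analysis for
robot-assisted surgery training sessions: a physiological stress estimate
from a wearable heart-rate band, hand kinematics from fiducial markers on
the console's master tool manipulators (MTMs), posture metrics from a
side-view pose-landmark track, a significance-tiered correlation screen of
the metric battery against the stress estimate, and a workload-targeted
skill classifier battery.  Because no public recording of such sessions is
available, a synthetic cohort generator with planted structure stands in
for study data and defines the conditions under which the pipeline is
validated.

## Stress index

The Baevsky stress index is computed per task window from the inter-beat
(RR) interval series:

    SI = AMo / (2 * Mo * MxDMn)

after rounding RR intervals to a 50 ms grid for noise reduction.  `Mo` is
the mode of the binned series (seconds), `AMo` the relative frequency of
the mode (percent), `MxDMn` the binned max-minus-min range (seconds).
Conventions the classical definition leaves open, fixed here and tested:

* rounding to the *nearest* bin, midpoints away from zero (825 -> 850);
* `MxDMn` computed on the binned series, consistent with the rounding
  being applied to the data as a whole;
* multimodal ties resolve to the smallest RR value;
* a window must contain at least 10 beats — mode and range statistics are
  meaningless below that;
* a constant binned series (MxDMn = 0) raises a degenerate-variability
  error rather than returning infinity.

With `Mo`/`MxDMn` in seconds and `AMo` in percent the index has the
familiar magnitudes (tens when relaxed, hundreds under sympathetic
stress).

## Hand kinematics

Marker detections arrive as axis-angle rotations and camera-frame
translations.  The translation's z-component is replaced by the RGB-D
depth estimate when present (it is more accurate than the size-based
estimate).  Poses are lifted to rigid transforms by the Rodrigues map and
rebased into the frame of a reference marker fixed to the armrest,
`H_k->ref = H_ref^-1 H_k`, which cancels any motion of the loosely
mounted camera; only the translation is kept, because the marker
placement on the MTMs discards orientation by design.  Frames missing
either marker are dropped and counted.

Per-hand metrics over the task window (resampled to a common 10 Hz grid):

* `std3d` — square root of the summed per-axis population variances;
* `range` — Euclidean norm of the per-axis extents (bounding-box
  diagonal); per-axis extents are also exported;
* `total_dist` — summed consecutive Euclidean steps;
* `avg_speed` — total distance over elapsed time;
* `jerk` — mean magnitude of the third position derivative, taken with
  the 5-point central stencil on linearly resampled gap-free segments.
  Gaps longer than 0.5 s are never interpolated across; segments are
  combined by duration weighting; jerk is norm-based rather than
  per-axis.

Bimanuality ratios divide the dominant (right; all study subjects were
right-handed, configurable) hand's `total_dist` and `range` by the
non-dominant hand's; a zero denominator flags the trial instead of
producing a value.

## Posture

A 33-point whole-body landmark model observed from the side provides the
right shoulder (id 12) and right elbow (id 14).  The primary metric per
joint is the time-averaged absolute vertical velocity
`sum(|dy|) / (t_end - t_start)`; the peak-to-peak vertical range is
exported as a secondary column, since the vertical-displacement notion
could be read either way.  Only absolute differences of y enter, so the
image-coordinate convention (y down) is immaterial.  The posture clock is
shifted by a per-trial manual offset before use, reflecting offline video
processing.

## Correlation screen

The metric table holds one row per trial: BSI plus 25 metrics (10 hand,
2 bimanuality ratios, 2 posture, 6 SURG-TLX workload answers each 1..20,
5 manually recorded task scores).  Degenerate metrics are flagged as
missing, never zero-filled, and removed pairwise per correlation, so each
report row carries its own pair count.  Each metric is screened against
BSI with a sample Pearson correlation; the p-value is two-sided from the
exact t distribution with n-2 degrees of freedom (two-sided is the
conservative choice; the screened hypotheses are signed, but sidedness is
a matter of convention and is left two-sided throughout).  Tiers:
p < 0.05 strong, 0.05 <= p <= 0.08 weak (closed interval at both
boundaries), otherwise none.  All trials are pooled across tasks and
subjects; no multiple-testing correction is applied, as the screen is
exploratory.  The report is deterministic: identical tables produce
byte-identical reports.

## Skill classification

Each SURG-TLX question is binarized against its cohort mean (below ->
expert-like 0, above -> novice-like 1, ties to 0).  Trial feature vectors
are the approximate entropies of eleven channels: instantaneous heart
rate (60000/RR resampled to the 10 Hz grid), right/left hand x, y, z, and
shoulder/elbow x, y.  ApEn uses the standard convention m = 2,
r = 0.2 * sd with Chebyshev distance and self-matches included; a
constant channel short-circuits to 0.  The implementation is vectorized
template counting; tests verify it against an independent
embedding/`cdist` construction to 1e-10.

Four classifiers are exhaustively grid-searched:

* decision tree — criterion {gini, entropy}; max_depth {None, 1..10};
  max_features {None, sqrt, log2, 0.1..0.9 step 0.1, 1.0 (all features),
  1 (single feature)}; splitter {best, random}: 616 combinations.  The
  documented endpoint "1" of the fraction range is admitted under both
  readings scikit-learn distinguishes;
* k-NN — n_neighbors 1..(smallest training-fold size); weights
  {uniform, distance}; metric {euclidean, manhattan, minkowski};
* SVM — C {1000..0.1}, kernel {poly, rbf, sigmoid, linear}, gamma
  {auto, scale, 1..0.0001}: 396 combinations;
* logistic regression — only usable solver-penalty pairs (liblinear/saga
  with l1 and l2; newton-cg/lbfgs/sag with l2) times 9 C values: 63
  combinations.

Cross-validation is leave-one-out or stratified k-fold with seeded
shuffling (default seed 7919); k = n degenerates to LOOCV exactly.  The
reported accuracy of a cell is the mean out-of-fold accuracy of the best
parameter combination; ranking by the best single fold is available
behind `aggregate="max"`, since "best train/test set" reporting is
ambiguous.  Features are deliberately not standardized.

## Synthetic cohort

The generator emulates the study design: three groups (novice, resident,
surgeon; skill 0 / 0.5 / 1), five subjects each, four two-minute console
tasks, with the last two of the nominal 60 trials dropped to mirror a
58-trial dataset.  Each trial draws a latent stress `s ~ U(0,1)`.

* **RR**: truncated Gaussian, mean `900 - 150 s` ms, sd `90 (1 - 0.7 s)`
  ms, floor 300 ms.  Higher stress compresses variability and raises the
  stress index (generation-level median SI rises monotonically in `s`).
  This is a histogram-level simplification — no beat morphology,
  ectopy, or autonomic spectra — which is all the index consumes.
* **Hands**: per-axis band-limited noise affinely rescaled into per-hand
  boxes.  Left box `0.05 + 0.06 s` m; right box fixed at 0.496 m with
  5% per-trial lognormal size noise (without that stress-independent
  variance the stress-linked jitter would be the only variance source in
  the right-box metrics and fake a correlation).  Left bandwidth 1.0 Hz;
  right bandwidth `0.345 - 0.22 s` Hz, so the dominant hand slows with
  stress.  The two anchors — box-diagonal ratio ~6.2 and path-length
  ratio ~1.7 at mid stress — fix the right-box size and bandwidth.
  A 2.5–4.5 Hz jitter with amplitude `0.5 + 1.0 s` mm drives the jerk
  metrics and the ApEn features.
* **Camera**: markers are emitted in camera frame through a slowly
  wobbling synthetic camera pose (0.03 rad / 5 mm rms, low-passed at
  0.2 Hz), so rebasing is exercised nontrivially; rebuilding the
  trajectories from the observations must reproduce the planted paths to
  1e-9 m.  Emitted depth equals the camera-frame z, so the depth
  substitution is a verified fixed point.
* **Posture**: baseline + slow drift + oscillation whose amplitude scales
  with `0.2 + 0.8 s` for both joints.
* **SURG-TLX**: physical fatigue and distractions follow
  `clip(round(1 + 12 s + N(0,2)), 1, 20)`; the other four questions are
  stress-independent discretized-Gaussian noise.
* **Manual scores**: Poisson counts with rates decreasing in skill and
  independent of stress; rings placed is Binomial(10, p(skill)).

The ground-truth table records the planted latents, and `PLANTED_SIGNS`
records each battery metric's expected correlation sign with BSI.  One
mediated effect is deliberately recorded as planted rather than null:
lower dominant-hand bandwidth concentrates the trajectory near its box
edges, so right-hand `std3d` rises with stress although the box is
unchanged.

What passing tests show — and do not show.  Recovery of planted signs and
tiers at n = 58 demonstrates that the pipeline's plumbing, statistics and
calibration behave correctly at study scale; it says nothing about
physiological validity, marker-detection noise, pose-model failure modes
(clothing, head position), or the true effect sizes in real consoles,
none of which the generator emulates.

## Problem sizes and numerics

Default validation sizes: 58 trials of 120 s at 10 Hz; 200 cohort
replicates for sign-recovery/power checks; 10,000 replicates at n = 53
for the type-I calibration of the strong tier (expected 5%); 500 random
series for the stress-index oracle (rel. 1e-12); 1000 poses for the
rotation oracle (1e-9); 50 series of length 200 for the ApEn oracle
(1e-10).  Classification in the end-to-end analysis uses stratified 5-
and 10-fold schemes over the full grids; LOOCV is available and tested on
smaller fixtures.  Tolerances reflect pure floating-point error for the
algebraic oracles and binomial sampling error for the calibration rates.

## Known limitations

* The generator plants monotone, roughly linear links; the screen is
  Pearson-based and would understate strongly nonlinear dependence.
* SI is right-skewed by construction; correlations are computed on the
  raw index (no log transform), matching common practice for this index.
* Jerk on a 10 Hz grid is bandwidth-limited; the 2.5–4.5 Hz jitter sits
  near Nyquist and its jerk is therefore grid-dependent, which is
  harmless for correlation screening but means jerk magnitudes are not
  comparable across sampling rates.
* The questionnaire binarization uses the cohort mean, so targets and
  therefore accuracies depend on cohort composition.
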