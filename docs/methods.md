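# Methods

This note documents the models, conventions and parameter choices behind
`dyadsync`, in the order data flows through the pipeline.  Everything
stated here is computed by the test suite or `scripts/acceptance.py`;
nothing is quoted from elsewhere.

## Study design emulated by the generator

The pipeline targets recordings of two seated strangers holding two
ten-minute conversations (a hobbies conversation and a collaborative
meal-planning task) filmed at 30 frames per second, in a cohort of 28
mixed (ASD-TD) and 16 control (TD-TD) dyads — 88 participants after
exclusion bookkeeping (excluding one member of a dyad always excludes the
partner too).  Cohort covariates default to the published cohort's
group-level age/IQ/sex distributions; they are configurable and purely
pass-through (no questionnaire scoring is modeled).

### Coupled time-series model

Each member of a dyad owns stationary unit-variance AR(1) latent
processes (coefficient `base_process`, default 0.9 — slow, strongly
autocorrelated movement streams).  For one channel with following
strengths `(c_a, c_b)` and lag `L` frames, the *weaker* follower's signal
is built first,

    first  = (1 - c_first) * own_latent + c_first * lag_L(partner_latent)

and the stronger follower then tracks the partner's *composite* signal,

    second = (1 - c_second) * own_latent + c_second * lag_L(first)

plus white measurement noise (sd 0.3 by default).  The sequential form
matters: coupling two members only to each other's latents makes their
*observed* signals nearly independent at high coupling, because each then
reproduces a different latent.  With the composite form, the follower's
peak windowed cross-correlation rises monotonically with `c` (measured ≈
0.30 / 0.40 / 0.71 / 0.88 at c = 0, 0.3, 0.6, 0.9 under the default
noise), and at `c = 1`, zero noise, the follower is an exact lag-L copy.
A consequence worth knowing: the model is leader-follower shaped — at
mutually high coupling the *leader's* own following score saturates low,
since truly mutual delayed imitation at a common lag would require strong
autocorrelation at twice the lag.  Mutual adaptation in control dyads is
therefore represented as moderate symmetric strengths (0.6), not extreme
ones.

Per-member observed channels: AU intensities `clip(2.5 + x, 0, 5)` (the
0-5 tracker intensity convention), pose angles `10x` degrees, body motion
energy `clip(1 + 0.4x, 0)`.  The three pose channels share a per-member
head latent (weight 0.7), and the body latent mixes that head latent at
`intrapersonal_coupling` (default 0.4) so intrapersonal head-body
coordination sits above chance.

### Dyad-type contrast

Defaults: control dyads draw both members' following strengths from
N(0.6, 0.1); mixed dyads draw the TD member from N(0.6, 0.2) and the
autistic member from N(0.2, 0.2) — an asymmetry with doubled spread,
encoding the *direction* of an elevated-and-more-heterogeneous adaptation
contrast.  No published effect sizes exist for these quantities; the
defaults are placeholders that make the contrast detectable at study
scale, not estimates.  Acceptance-scale classification therefore
validates the machinery, not any clinical effect size.  The generator
does not emulate: tracking dropouts (masks are full by default;
preprocessing is exercised with constructed gaps), task-specific
behavior differences, non-stationarity within a conversation, or
individual movement-quantity differences (so the MovEx model carries
little class signal under defaults — by design).

### Rendered motion fixture

`render_motion_frames` writes a float-grayscale stack whose ROI pixels
share one intensity that drifts by exactly the planted series value per
frame (cumulative-sum levels, static random texture outside the ROI).
Feeding it back through the motion-energy module with `noise_threshold=0`
recovers the series with identity scaling.  It is a synthetic fixture for
the pixel-difference machinery, not rendered video.

## Motion energy

Color frames collapse to luminance (0.299 R + 0.587 G + 0.114 B).  The
energy between consecutive frames within an ROI is the sum of absolute
grayscale differences exceeding `noise_threshold`, divided by the ROI
pixel count.  The threshold defaults to 10 grayscale units (a
conventional sensor-noise floor; configurable), per-area normalization
keeps differently sized head and body ROIs comparable (a raw-sum flag
exists), and the first frame's energy is defined as 0 so the series keeps
the stack's length.  ROIs are user configuration — axis-aligned, 0-based,
half-open pixel rectangles.

## Windowed cross-lagged synchrony

### Preprocessing

Frames with tracker confidence below 0.75 are invalidated; interior
invalid gaps of at most `max_gap_frames` (default 15 ≈ 0.5 s) are
linearly interpolated and re-validated; longer gaps stay invalid.  A
channel whose remaining invalid fraction exceeds 10% is flagged unusable
— flagged, never silently dropped — and propagates an all-missing summary
with a reason.

### Correlation grid

For window start w and lag k ∈ [-L, +L], the first series' segment
starts at `w + max(-k, 0)` and the second's at `w + max(k, 0)` (both
length W).  Positive lag therefore always means *the second series
trails the first*; this sign convention is fixed pipeline-wide and
asserted in tests.  Anchoring the pair symmetrically (rather than
holding the first series' window fixed) makes the pooled-direction
analysis exactly symmetric under argument swap, which the intrapersonal
summary relies on.  Windowing is full-overlap: w advances by
`step_frames` while `w + W + 2L <= T`, so no zero padding ever occurs
and the window count is `floor((T - W - 2L)/step) + 1`.

Entries are missing (NaN) when fewer than `min_valid_fraction` (default
0.8) of the overlapping frames are jointly valid, or when either segment
is constant over the jointly valid frames.  Valid-only (pairwise
complete) Pearson is used when masks intersect a window; an einsum fast
path handles fully valid data and matches the masked path to ~1e-15.
Series are globally standardized first (Pearson is affine-invariant) so
the moment-based windowed computation stays numerically stable; a
variance guard (1e-14 relative) routes near-constant windows to missing
rather than returning garbage correlations.

### Peaks, directions, summaries

Per window, the peak over one lag half: `A_leads` scans k >= 0,
`B_leads` scans k <= 0, `pooled` scans all lags; lag 0 belongs to both
halves (simultaneous matching is both leading and following).  The
default peak rule takes the maximum signed correlation (synchrony as
in-phase adaptation); a max-absolute rule is available.  *Following* for
a participant is the `A_leads` profile of `wclc(partner, self)` — their
own signal trailing the partner's.  Correlations are summarized without
Fisher-z transformation (peaks are bounded well away from ±1 in realistic
noise; the choice is a convention, applied uniformly).

The seven summary statistics use sample (n-1) sd, moment skewness g1 and
excess kurtosis g2 over non-missing windows; fewer than two non-missing
windows gives an all-missing summary, and an exactly constant profile
reports sd 0 with skewness/kurtosis undefined (NaN), left for
training-time imputation downstream.

Default window parameters (configurable per channel group): facial and
head channels 5 s windows, 1 s step, ±2 s lags; body 10 s windows, 2 s
step, ±5 s lags — conventions reflecting the slower time scale of gross
body movement, not reproductions of any published setting.

### Pseudo-dyad baseline

Random re-pairings of non-partners (genuine partners never paired),
each scored by the following summary, give a chance distribution with a
quantile function.  Uncoupled simulated dyads fall inside its central
95%; strongly coupled ones exceed its 97.5th percentile.

## Features and labels

- Global head movement: per-frame Euclidean norm of the change in
  (pitch, yaw, roll); first frame 0.
- Total head/body movement: mean over valid frames (a rate, robust to
  how many frames survived preprocessing).
- Facial expressiveness: mean AU intensity over valid frames and usable
  retained AUs.
- Retained AU set: 12 intensity channels (AU01, 04, 06, 07, 10, 12, 15,
  17, 20, 25, 26, 45), config-overridable; 12 x 7 stats x 2 tasks gives
  the fixed FACEsync width of 168.  Model widths 168/56/14/14/6 are
  asserted at assembly, which preserves missingness (imputation happens
  only inside CV training).
- Feature names encode `channel|task|statistic` and round-trip through a
  parser.
- Labels: dyad type by default (both members of a dyad share the label;
  mixed is the positive class), individual diagnosis as a variant.
- Cohort table: rank-sum tests (normal approximation; Welch-t behind a
  flag) for age and both IQ measures with Benjamini-Hochberg adjustment
  across the three tests, and a Yates-continuity-corrected chi-square of
  independence for sex x group.  On the cohort's printed margins (18/10
  female/male ASD, 26/34 TD) the corrected statistic is 2.57, p = 0.109;
  without correction it would be 3.35, so the correction is load-bearing.

## Classification

Fold construction assigns *dyads* (never individuals) to folds,
stratified by class via largest-remainder counts with the two classes'
remainder dyads stacked on opposite folds, ties broken by a seeded
shuffle.  With 44 dyads and 11 outer folds every test fold holds exactly
4 dyads = 8 participants ≈ 9% of the sample.  Defaults: 11 outer folds x
10 repetitions, 10 inner folds x 1 repetition (both configurable; the
desk-scale tests and the acceptance script use 2 outer repetitions and 5
inner folds, with problem sizes stated where used).

Per outer fold, preprocessing (per-feature z-standardization, then
median imputation of missing cells on the standardized scale) and the
choice of C are fitted strictly on outer-training rows; the inner loop
refits preprocessing per inner split, scores each C on mean inner
balanced accuracy, and ties go to the smallest C.  An instrumented
leakage guard raises if preprocessing statistics would touch test rows.
The base estimator is the LIBLINEAR L2-regularized L2-loss linear SVM
(tolerance 1e-6, iterations capped at 5000 inside the engine with
convergence warnings surfaced; 20000 in the standalone trainer) with
inverse-class-frequency cost weights normalized to mean 1.  The engine
calls the LIBLINEAR entry point directly in its hot loop — identical
solver and solution as the public estimator (asserted in tests) without
per-call validation overhead.  The C grid defaults to 11 log-spaced
points 2^-6 … 2^4.

Out-of-fold decision scores are aggregated across outer repetitions by
mean and thresholded at 0 (score 0 goes to the positive class); the
metric panel (sensitivity, specificity, BAC, rank-statistic AUC with
midrank ties, PPV, NPV) is computed from the aggregated predictions.
The aggregation rule is a documented convention — per-repetition
majority voting would be an alternative.

## Inference

- **Permutation test**: each of the n_perm (default 1000; reduced modes
  provided) draws shuffles dyad-type labels across dyads — members
  permuted in pairs, so class sizes are preserved exactly and no dyad is
  split — rebuilds the fold structure for the permuted labels, reruns
  the full nested CV and records BAC.  p uses the add-one estimator and
  never reaches 0.  `null_outer_permutations` reduces outer repetitions
  inside null reruns only (the observed statistic keeps the full
  setting).  Results are annotated at both alpha 0.05 and 0.005.
  Calibration: on null data the reduced test (99 draws) rejects in 3 of
  100 repetitions at alpha 0.05.
- **Stacking**: a Gaussian-kernel hinge-loss SVM over base models'
  aggregated out-of-fold decision scores (training-fold scores are never
  available to it), wrapped in the identical dyad-grouped nested CV; the
  kernel width grid is the median-heuristic gamma of each outer training
  set times {0.25, 0.5, 1, 2, 4}, tuned jointly with C on inner BAC.
- **Importance**: cross-validation ratio = mean weight / standard error
  across the stored CV models (the outer-fold x repetition models; a
  zero SE yields an explicit ±inf), and sign-based consistency = fraction
  of models agreeing with the majority sign (in [0.5, 1]).
- **Covariate correlations**: Pearson r of decision scores against
  covariate columns with Benjamini-Hochberg adjustment across covariates;
  constant covariates are flagged NaN.
- **Report**: a deterministic plain-text table (one row per model, sorted
  by BAC, permutation p annotated at both alphas, top features by
  |cv ratio|) from a run directory of scores/metrics/weights artifacts;
  every run can also write a manifest (seed, config hash, versions).

## Degenerate inputs and numerical conventions

Constant profiles/features: sd 0, undefined moments as NaN, constant
features standardized with sd 1.  Single-class truths: AUC NaN, BAC
reduces to the defined rate.  Zero-variance windows: missing, never ±1.
All randomness flows from integer seeds through named generators; no
global random state is touched, and identical seeds give bit-identical
results end to end.

## Known limitations

- The generator's coupling magnitudes and the AU/pose/body signal scales
  are conventions; passing tests demonstrate the estimator and CV
  machinery, not clinical effect sizes or tracker noise behavior.
- The leader-follower generative form cannot express strong *mutual*
  delayed imitation at a single shared lag (see above).
- Exact window/lag settings, the retained-AU set and the preprocessing
  chain of any particular real deployment are configuration, and results
  will depend on them.
- No dynamic time warping, phase/wavelet synchrony, or time-resolved
  synchrony curves; the windowed peak profile is the only synchrony
  representation.
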