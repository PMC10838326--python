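# dyadsync

Interpersonal synchrony features and dyad-grouped SVM classification for
naturalistic social-interaction recordings.

## The problem

When two people converse, they continuously adapt their facial
expressions, head motion and body movement to each other.  In autism
spectrum disorder (ASD) this reciprocal adaptation is atypical, which
makes *the dyad* — not the individual — a promising unit of analysis for
objective, rating-free diagnostic classification.  `dyadsync` implements
that analysis end to end for recordings of two ten-minute conversation
tasks filmed at 30 frames per second:

1. **Per-frame behavioral channels** — facial action-unit (AU)
   intensities and head pose from OpenFace-style tracker CSVs, and a body
   **motion-energy** channel (mean absolute grayscale pixel change inside
   a fixed region of interest) computed by the package or read from
   MEA-style CSVs.
2. **Windowed cross-lagged synchrony** — for two series x, y, Pearson
   correlations r(w, k) per window w and lag k (positive lag = y trails
   x), the per-window peak over one lag direction, and seven summary
   statistics of the peak profile (mean, median, sd, min, max, skewness
   g1, excess kurtosis g2).  A participant's **following** of the partner
   is the peak profile in the direction where their own signal trails the
   partner's.
3. **Five base models** with fixed feature dimensions per participant
   (both tasks combined): FACEsync 168 (12 AUs x 7 stats x 2 tasks),
   HEADsync 56 (global head movement + pitch/yaw/roll), BODYsync 14,
   INTRAsync 14 (own head x body coordination), MovEx 6 (total head/body
   movement and facial expressiveness).
4. **Classification** — participants labeled by *dyad type* (mixed ASD-TD
   vs control TD-TD; both members share the label), L2-regularized
   L2-loss linear SVMs with inverse-class-frequency hyperplane weighting,
   inside an 11-fold x 10-repetition outer / 10-fold inner dyad-grouped,
   stratified nested cross-validation optimizing balanced accuracy
   BAC = (sensitivity + specificity)/2.
5. **Inference and interpretation** — dyad-paired label-permutation tests
   (p = (1 + #{null BAC >= observed}) / (1 + n_perm)), Gaussian-kernel
   decision-score stacking in the identical CV frame, feature importance
   by cross-validation ratio (mean weight / SE across CV models) and
   sign-based consistency, and pseudo-dyad (random re-pairing) baselines.

Because the clinical recordings such analyses are run on cannot be
shared, the package ships a first-class **synthetic dyad generator**:
AR(1) latent processes per member, with a follower's observed signal
mixing their own latent with the partner's lag-shifted signal at a
per-member coupling strength.  Coupling is the single dial connecting the
generator to every downstream estimate, so the whole pipeline is testable
without any data download.

## Worked example

`examples/classify_dyad_types.py` simulates the full 44-dyad cohort with
a strong planted coupling contrast, computes body-synchrony features and
runs the nested CV:

```
BODYsync (14 features, 88 participants)
  BAC   98.4%   (balanced accuracy of out-of-fold predictions)
  AUC  1.000
  sens 100.0%  spec  96.9%  PPV  98.2%  NPV 100.0%
chance is 50% BAC; a large planted contrast should score >= 90%
```

BAC is computed from out-of-fold decision scores aggregated across outer
repetitions, so ~98% means the planted dyad-type contrast survives the
whole feature/CV pipeline; label-permuted inputs score ~50%.  The other
examples cover simulation + synchrony summaries, the motion-energy round
trip, and permutation testing + stacking:

```bash
python examples/simulate_cohort_and_synchrony.py
python examples/motion_energy_roundtrip.py
python examples/permutation_and_stacking.py
```

## Layout

- `src/dyadsync/synthetic.py` — rosters, exclusions, coupled time series,
  rendered motion fixtures
- `src/dyadsync/motion_energy.py` — grayscale conversion, ROI
  frame-difference energy
- `src/dyadsync/synchrony.py` — preprocessing, windowed cross-lagged
  correlation, peak profiles, summaries, pseudo-dyad baselines
- `src/dyadsync/features.py` — movement measures, feature assembly,
  labels, cohort statistics
- `src/dyadsync/classification.py` — CV scheme, weighted linear SVM,
  nested engine, metrics
- `src/dyadsync/inference.py` — permutation tests, stacking, importance
  maps, covariate correlations, reports
- `docs/methods.md` — model assumptions, parameter choices, limitations

ROI configs are plain text (`label,x0,y0,x1,y1`, 0-based, half-open
pixel rectangles).  Face-tracking CSVs use the OpenFace column layout
(`frame, timestamp, confidence, success, pose_Rx/Ry/Rz, AU.._r ...`), so
real tracker output drops in directly.
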