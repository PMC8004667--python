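# Methods

`fogpipe` implements a window-level freezing-of-gait (FOG) classification
pipeline for multichannel wearable gait data: plantar-pressure-derived
signals (ground reaction force, centre of pressure) and lower-limb inertial
sensors. Because no public dataset with this exact channel set exists, the
package ships a synthetic cohort generator that emulates the statistical
structure the classifier exploits; everything downstream of the generator
(windowing, features, selection, boosting, evaluation) is the analysis
proper and applies unchanged to real recordings with the same channel
layout.

## Data model

A trial is 30 channels sampled at 100 Hz: per side, total ground reaction
force (GRF, N) and centre of pressure (COP) in the anterior–posterior (AP)
and mediolateral (ML) axes (mm); plus four IMUs (ankle and thigh, left and
right), each with 3-axis acceleration (m/s²) and 3-axis angular rate
(deg/s). FOG episodes are annotated as `[onset, end]` intervals in seconds.
Units are conventions only — every feature is covariant under consistent
rescaling, and the two ranking methods are invariant to per-feature affine
rescaling.

## Windowing and labels

Trials are cut into 1 s windows advanced by 0.2 s (windows start at sample
0 of each trial; the grid restarts per trial). Each window gets exactly one
label:

- **FOG** — window entirely inside an episode;
- **Pre-FOG** — window entirely inside the 2 s segment before an onset;
- **Pre-FOG-Transition** — window straddling an onset while staying inside
  pre-freeze + episode;
- **No-FOG** — everything else, including windows that touch ordinary
  walking before the pre-freeze segment or after the episode end.

**Total-FOG** = Pre-FOG ∪ Pre-FOG-Transition ∪ FOG is the training target.

Interval convention: a window occupies the closed time interval
`[start, start + 1 s]`; episodes are closed, the pre-freeze segment is
half-open `[onset − 2, onset)`. With an onset on the 0.2 s grid this yields
exactly 5 Pre-FOG and 5 Pre-FOG-Transition windows per episode — the
canonical geometry the labeling is defined by. A consequence is that the
window ending exactly at the onset counts as Transition (it touches the
episode at a single instant); degenerate zero-length episodes are ignored
entirely. A window covering pre-freeze, a whole short episode, and
post-episode walking is No-FOG (it contains No-FOG instances).

## Features (861)

- **Time domain, plantar pressure only (25 over 13 types):** AP-COP path
  reversals (count of sign changes of the first difference, with zero
  differences inheriting the previous sign; total duration and total
  absolute displacement between consecutive reversal points), ML-COP
  deviations (maximal runs where the per-sample first difference exceeds
  0.5 mm; count, total seconds, total displacement), coefficients of
  variation (sample SD / |mean|) of COP position, velocity and acceleration
  in AP and ML, and one two-footed count of strict-majority (>50 % of total
  GRF) weight shifts.
- **FFT (8 × 38 = 304):** untapered DFT magnitude over non-negative bins,
  DC excluded everywhere. Total power (sum of squared amplitudes), dominant
  frequency (bin with the largest amplitude, ties to the lowest), max/min/
  mean amplitude, power in the locomotion band [0.5, 3) Hz and freeze band
  [3, 8] Hz (half-open at 3 Hz so the bands partition), and the freeze
  index = freeze power / (locomotion power + 1e−12).
- **Haar DWT (14 × 38 = 532):** single-level orthonormal Haar transform
  (so Parseval's identity holds exactly); variance, max/min/mean, and
  max/min/mean energy (coefficient²) of the approximation and detail
  vectors.

The 38 FFT/WT inputs are, per side: GRF; COP position, velocity,
acceleration in AP and ML (14 plantar-pressure signals, 333 features
including time-domain); and ankle/thigh 3-axis acceleration and angular
rate (24 IMU signals, 528 features). Before COP derivations, a foot's GRF
below 5 % of the two-foot total is zeroed (swing phase) and its COP held at
the last stance value (leading samples backfilled); COP velocity and
acceleration are first/second differences times fs and fs², padded by
replication. CV denominators below 1e−9 in magnitude report CV = 0.

## Feature selection

Both methods rank features against the binary Total-FOG vs No-FOG labeling
on the training participants of each cross-validation fold (re-run per
fold; no held-out data enters selection).

- **Relief-F** (k = 200 neighbours, 2000 updates): features min-max
  normalised; instances sampled without replacement (fresh permutations if
  updates exceed rows); nearest hits/misses by Manhattan distance; hit
  differences decrease a feature's weight, miss differences (prior-weighted)
  increase it; k is capped at the smallest class size minus one with a
  logged warning. Ties in the final weights resolve to registry order.
- **mRMR** (MID criterion): equal-frequency 10-bin discretisation; greedy
  forward selection maximising I(feature; class) − mean I(feature;
  selected); first pick maximises relevance alone; top 100 retained.

## Classifier

RUS-boosting: discrete AdaBoost in which each cycle's depth-limited CART is
fitted on all minority-class rows plus a weight-proportional random
undersample (without replacement) of the majority class of equal size — so
every cycle trains on a class-balanced subset — while the weighted error,
stage weight α = learn_rate · ½ ln((1−err)/err), and multiplicative weight
update use the full training set. Cycles stop at 100, on err ≥ 0.5 (tree
discarded), or err = 0 (tree kept). Prediction is the α-weighted fraction
of positive tree votes, thresholded at 0.5; test data are never resampled.
The "5 or 10 split" budget caps the *number* of internal splits via
best-first growth (`max_leaf_nodes = splits + 1`); a plain depth cap is
available behind `split_budget="depth"`. Training is made row-order
invariant by sorting rows on (label, feature values) before any random
draw. If every tree is rejected (e.g., all-constant features), the model
falls back to predicting the majority class with a logged warning.

## Evaluation

Leave-one-freezer-out (LOFO): one fold per freezing participant;
nonfreezers are always in the training set. Within each fold one model is
trained on the Case 1 target (Total-FOG) and evaluated against five target
definitions — Case 1 Total-FOG, Case 2 Pre-FOG, Case 3 Pre-FOG ∪
Transition, Case 4 Transition, Case 5 FOG — always against the No-FOG
nontarget, so specificity is identical across cases by construction.
Windows outside a case's target/nontarget sets are excluded from that
case's metrics; a case with zero target windows reports sensitivity as
missing, never as 100 %. Aggregates are the mean and population SD over
freezer folds only; nonfreezer specificities come from separate hold-out
folds and are listed alongside. The model grid is 2 ranking methods × 8
feature counts (5–100) × 2 split budgets = 32 configurations; "best" is
the highest freezer-mean balanced accuracy, (sensitivity + specificity)/2,
on Case 1 — the selection criterion is a package choice, as is evaluating
nonfreezer specificity only for the selected configuration.

## Synthetic cohort

The generator emulates the *band structure and COP geometry* the features
measure, not biomechanics. Defaults: 11 participants, 7 freezers, 2 trials
of 60 s each at 100 Hz (≈22 min of walking, ≈6500 windows — a desk-scale
analogue of a laboratory session), per-leg step frequency 1 Hz, 1.5
episodes/min for freezers with durations uniform on [3, 8] s, 2 s
pre-freeze ramps. Episodes come from a thinned Poisson process: candidates
that would start before a full pre-freeze margin, collide with the previous
episode plus margin, or overrun the trial are dropped (logged, not an
error), so every episode has a clean 2 s pre-freeze segment.

Signal model (additive sinusoids + Gaussian noise):

- Normal gait: GRF alternates between feet via a smoothed square wave at
  the step frequency with double-support overlap; COP sweeps each stance;
  IMU channels carry 1–2 Hz harmonics. All locomotion amplitudes are scaled
  by a per-participant vigour factor (lognormal, σ = 0.35), per-participant
  body weight (σ = 0.15) and COP excursion (σ = 0.2) factors, and a slow
  (0.05–0.12 Hz) ±35 % within-trial modulation. This variability is what
  keeps absolute signal power from being a trivial class separator — as in
  real gait — so the class signal lives in *where* the power sits
  (dominant frequency, freeze index), not in how much there is.
- During FOG (intensity f ramps 0→1 linearly over the 2 s pre-freeze, holds
  at 1, drops at episode end): the stepping phase that drives weight
  transfer halts, leaving a reduced-amplitude weight sway plus a freeze-band
  wobble ("alternating leg trembling") that never completes a transfer;
  COP excursion shrinks to 20 %; limb oscillation persists (the freeze
  arrests weight transfer, not limb motion) at 70 % amplitude; and a
  two-tone 4–7 Hz trembling component, scaled by `freeze_band_gain` and a
  per-participant tremor-severity factor, is added to shank IMU channels,
  COP, and the weight-share signal.
- Per-channel Gaussian noise with SD `noise_sd` × channel scale.

What the generator does **not** emulate: realistic waveforms or
musculoskeletal dynamics, turning/dual-task context, sensor drift or
artefacts, heterogeneous FOG subtypes, or label noise from video
annotation. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it recovers a planted band-shift signature
under realistic amplitude variability — not that the reported operating
points transfer to clinical data. The pre-freeze linear ramp in particular
is an *assumption*: real pre-freeze signal characteristics are
hypothesised, not established, and nothing here validates them.

## Numerical choices

- FFT without taper; DC excluded from all spectral features; dominant-
  frequency ties take the lowest bin.
- Freeze-index and CV denominators guarded by 1e−12 / 1e−9.
- Interval comparisons in labeling use a 1e−9 s tolerance.
- Boosting α capped via err floor 1e−10; majority draw is
  weight-proportional without replacement.
- Reliance on fixed seeds throughout: a single pipeline seed derives each
  stage's seed (CRC-based, < 2³¹); identical configs reproduce identical
  artifacts byte-for-byte.

## Known limitations

- A held-out participant whose tremor or gait amplitudes are extreme can
  defeat the participant-independent model (one synthetic fold shows this
  clearly); this mirrors the fold-to-fold spread seen in participant-
  independent FOG studies and is a property of the problem, not a bug.
- Relief-F at 2000 updates × ~6000 rows × 861 features dominates runtime
  (~25 s per fold); the LOFO pass with per-fold selection takes a few
  minutes at the default cohort size.
- mRMR's equal-frequency binning can merge quantiles on heavily tied
  features (bin count silently drops), which weakens but does not bias its
  relevance estimates.
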