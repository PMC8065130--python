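# Methods

This note documents the signal model, the algorithmic conventions, the
parameter defaults and the deliberate design choices behind the package.
Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

A body-worn triaxial accelerometer records acceleration in gravity units
(g) at a uniform rate (reference 100 Hz; the bundled cohorts use 10 Hz to
keep runs fast — every time-domain parameter is expressed in seconds and
scales with the rate). Non-wear time — spans when the device is not on
the body — must be identified and excluded before activity summaries are
computed. The difficulty is that a stationary device and a sleeping or
sedentary wearer produce nearly identical, noise-floor-level signal. The
package's central idea: the *interior* of a quiet span is uninformative,
but the few seconds *around* its edges are not — removal and
re-attachment leave a short, high-dynamics motion signature, while quiet
wear does not.

## Time conventions

* Samples are 0-indexed; sample `i` occupies time `i / rate_hz` seconds.
* All intervals are half-open `[start, stop)` in seconds from recording
  start. Detection, merging, refinement and scoring compose without
  ambiguity under this convention.
* Per-second rasterization marks second `t` as covered when intervals
  overlap at least 0.5 s of `[t, t+1)`. The majority rule is a package
  convention (scoring is defined on 1-s intervals, but no rounding rule
  for fractional boundary seconds is canonical); it is symmetric and is
  applied identically to predictions and ground truth.

## Episode detection

Quiescence is judged per tumbling 1-min bin aligned to the recording
start: a bin is quiescent when all three per-axis standard deviations are
at or below 4 mg, a threshold just above the reference device's noise
floor. Implementation choices:

* **Population SD** (divisor N). With ≥ 600 samples per bin the
  difference from the sample SD is far below the threshold granularity;
  the choice is configurable.
* **Tumbling bins**, not sliding: a forward pass over consecutive 1-min
  intervals. Sliding bins would shift episode edges, which 1-s refinement
  re-establishes anyway.
* **Merging is inclusive**: a gap of exactly `merge_min` minutes merges.
* **Order is fixed**: detect → merge → refine. Refinement never triggers
  a second merge pass, even if refined edges close a gap — the merged
  episode is the classification unit.
* A trailing partial minute is ignored by detection but reachable by
  refinement.
* Bin alignment to recording start (rather than clock minutes) is a
  package convention.

Edge refinement extends each episode outward in 1-s steps while every
added second keeps all three per-axis SDs ≤ 4 mg, stopping at the first
failing second or the recording boundary; an episode never shrinks. A
partial leading/trailing block shorter than the step is included when it
is itself quiescent, so refinement can reach the exact recording
boundary.

## Feature windows

Windows are raw slices — no filtering, no scaling — of
`round(window_s x rate_hz)` rows taken immediately before the refined
start and immediately after the refined stop. A side is absent when it
would cross a recording boundary. Both windows of an episode share one
label. For training, an episode is labelled non-wear when more than 50 %
of its span lies inside true non-wear intervals (the gold labels come
from the simulator; the overlap threshold is configurable).

Splitting is 60/20/20 (train/validation/test), stratified by label at the
window level; a participant-level split unit is available to prevent
cross-person leakage. Class balancing by random duplication of the
minority class is applied **after** splitting and to the training split
only — duplicating first would leak copies of training windows into
validation and test.

## The classifiers

Four 1D CNN architectures classify a window as wear (0) or non-wear (1):

| arch | convolutions (filters × kernel @ 100 Hz) | pooling | dense |
|------|------------------------------------------|---------|-------|
| V1 | 10×15 | — | 10 |
| V2 | 10×15, 50×10 | — | 10 |
| V3 | 20×15, 100×10, 100×5 | — | 10 |
| V4 | 10×15, 50×10 | max-pool 2 after each conv | 10 |

All convolutions are valid, stride 1, ReLU; the last feature map is
flattened into the dense stack; the output is a single sigmoid unit. The
V2 layer dimensions are pinned by two exact constraints: the parameter
count must be 144,031 for a 300×3 input and 344,031 for a 700×3 input.
Under valid stride-1 convolutions the count difference per input sample
equals (last-conv filters) × (dense units), which forces that product to
500; the first kernel of 15 then closes the 300-input equation. The
second conv's kernel size cancels out of both counts and is set to 10.
Kernel sizes are defined at the 100 Hz reference and scaled with the
rate, with a floor of ~0.5 s of signal so the removal signature stays
inside a receptive field at low rates; at 100 Hz the scaling is the
identity, leaving the pinned counts untouched.

**Gravity-offset handling.** The model's first layer subtracts each
axis's within-window mean (a fixed, parameter-free operation). Within a
3-s window gravity is an approximately constant per-axis offset set by
device orientation, and the discriminative content is entirely in the
dynamics around it. A network trained on a cohort of hundreds of
participants can learn this invariance from data; on the package's
deliberately small synthetic cohorts it demonstrably cannot (held-out
window accuracy 0.85–0.97 without the layer versus 0.98–1.0 with it), so
the invariance is built in structurally. Feature windows themselves
remain raw slices, and the layer adds no trainable parameters.

Training: Adam (lr 0.001, β₁ 0.9, β₂ 0.999), binary cross entropy
(computed in logit form for numerical stability), minibatches of 32
(unreported upstream; config-exposed), up to 250 epochs, early stopping
on validation loss with patience 25 and restoration of the best-epoch
weights. Weight initialisation is He-style fan-in scaling (standard for
ReLU stacks). Runs are single-threaded-deterministic given the config
seed. `train_with_restarts` offers validation-loss model selection over
seeded restarts for small-data robustness; the default protocol is a
single run. The decision threshold is 0.5 with probability ≥ threshold
classified 1 (tie goes to non-wear).

## Pipeline decision rule

Per episode: both window classes are combined with a logical operator
(default AND — both sides must carry the signature), and an absent side
takes the edge default (default non-wear). The defaults correspond to the
best-performing hyperparameter combination (merge 5 min, AND,
edge-default non-wear). Episodes decided wear contribute no non-wear
seconds even though they are below the SD threshold — separating quiet
wear from non-wear is the entire point of the classification stage. When
a merged episode is decided wear its constituent sub-episodes are not
re-tested individually. Preceding/following windows of neighbouring
episodes are extracted independently and may overlap in time.

## Baselines

* **XYZ**: maximal runs of quiescent 1-min bins (all three per-axis SDs
  ≤ threshold, menu 4–7 mg) kept when the run reaches the interval length
  (menu 15–120 min). The interval rule is read as *duration must reach at
  least the interval* — the count-based convention all such detectors
  share.
* **VMU**: identical run logic on the SD of the per-sample vector
  magnitude √(x²+y²+z²) within each bin.
* **HEES** (GGIR convention): sliding windows of 30/60/135 min at a 1-min
  step; a window is non-wear when ≥ 2 of 3 axes have SD < 13 mg or ≥ 2 of
  3 axes have range < 50 mg; qualifying windows are unioned. The 135-min
  variant's further tuned values live upstream; here they remain the
  GGIR defaults and are config-exposed, documented as provisional.

Because each requires quiescence for its full interval, any episode
shorter than the interval is invisible to it — the structural limitation
the pipeline removes.

## Evaluation

Predictions and truth are rasterized to per-second labels; seconds
accumulate into TP/FP/FN/TN; accuracy, precision, recall and F1 follow
the standard formulas with F1 the harmonic mean of precision and recall.
Degenerate conventions: with no predicted and no true positives the
positive-class metrics are 1.0 (needed for all-wear participants); if
exactly one denominator is empty with TP = 0 the undefined metric is 0.
Cohort values are means over participants with 95 % normal-approximation
confidence intervals (1.96·SD/√n; half-width 0 for n = 1); a bootstrap
alternative would be a drop-in replacement and across-participants is the
package default. The scored duration is the recording duration truncated
to whole seconds.

The hyperparameter grid evaluates all 5 × 2 × 2 = 20 combinations of
merge distance (1–5 min), operator (AND/OR) and edge default
(wear/non-wear), optionally on a 50/50 participant split; the training
grid enumerates 9 window sizes (2–10 s) × 4 architectures = 36
configurations.

## Synthetic cohorts

The simulator generates the signal classes the algorithm must tell apart;
its defaults define the package's study conditions.

| parameter | default | rationale |
|-----------|---------|-----------|
| non-wear noise SD | 2 mg | sensor noise floor, safely below the 4 mg threshold |
| active-wear noise SD | 50 mg | movement well above threshold in every minute |
| episode menu | active 6–15 min, sedentary 6–15 min, non-wear 2–30 min | see below |
| transient duration / amplitude | 1–3 s, 0.5–2 g | brief, vigorous handling motion |
| transient band | 1.5–8 Hz (clipped to 0.35·rate) | brisk jerk, resolved at low rates |
| posture-burst rate / amplitude / band | 4 h⁻¹, 0.15–0.35 g, 0.3–1.2 Hz | slow, small postural shifts |
| artificial-spike probability | 0.3 per episode | nudges of the unworn device, ≥ 90 s from the edges |

Signal model per segment: a random unit orientation carries gravity;
active wear adds band-limited Gaussian noise and drifts slowly between
orientations; sedentary wear is the constant gravity projection plus
noise-floor noise with occasional posture bursts (and **no** transient at
its boundaries); non-wear is the constant projection plus white noise.
Removal transients occupy the 1–3 s immediately before each interior
non-wear start, attachment transients the seconds after its stop; both
are tri-axial oscillations under a Hann envelope riding on an
orientation interpolation — handling the device excites all three axes,
unlike a single-axis posture shift.

Scheduling choices that keep labels well-defined:

* Non-wear episodes are bracketed by **active** wear and recordings start
  and end with active wear: devices are handled while the wearer is up
  and moving. This also keeps the edge-default hyperparameter inert on
  simulated truth; edge-default behaviour is exercised with directly
  constructed recordings in the tests.
* Wear bouts (6–15 min) always exceed the largest explored merge gap
  (5 min), so merging only ever bridges artificial movement *within* a
  quiet span, never across a genuine wear bout. Without this, merged
  episodes would mix wear and non-wear time and the training labels would
  be incoherent.
* Episode boundaries fall on whole seconds, making the ±1 s edge-recovery
  check exact.
* The episode turnover (bouts of minutes, not hours) gives a 12-participant,
  6-h training cohort a few hundred labelled windows — enough to train the
  V2 network; non-wear episodes of 2–30 min sit entirely below the 60- and
  90-min baseline intervals, so the interval-limitation comparison is
  structural, not statistical.

Each participant's signal derives from an independent substream seeded by
`(seed, participant_index)`; identical configs reproduce cohorts
bit-for-bit.

**What passing tests do and do not show.** The simulator reproduces the
statistical structure the algorithm relies on — SD regimes on either side
of the threshold, distinctive edge signatures, quiet wear without them,
short episodes, artificial movement — but not device-specific noise
spectra, biomechanical gait, diurnal rhythm, or the true waveform of
removal motions, which is unknown for the restricted reference data.
Results on synthetic cohorts therefore validate the pipeline's mechanics
and its qualitative advantage over interval detectors; they do not
predict numeric performance on any particular device or cohort.

## Problem sizes

Bundled experiments use 10 Hz recordings, 6-h cohorts of 20 participants
(12 train / 8 held-out), 3-s windows, and the default training protocol;
these sizes are the package's reference configuration for reproducible
desk-scale runs, with 100 Hz remaining the documented device-reference
rate.

## Known limitations

* The CNN is a from-scratch numpy implementation: correct and
  deterministic, but not optimised for large inputs (no FFT convolution,
  no threading); at the bundled problem sizes training takes seconds.
* HEES_135's upstream-tuned thresholds are not reproduced, only its
  interval length; its defaults are the GGIR ones.
* The 0.5-s coverage rule for rasterization and the >50 % episode-label
  overlap rule are package conventions, config-exposed.
* Participant-level splitting is available but the default split unit is
  the window, matching the 60/20/20 protocol on pooled windows.
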