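# Methods

## Problem and pipeline

Fatigue changes equine gait: after a standardized exercise test (SET),
walking stance duration lengthens, trotting swing duration shortens, and
limb excursions (longitudinal displacement, hind-limb pro/ret range of
motion) shrink.  `equigait` detects these changes from seven body-mounted
IMUs and classifies each horse-trial as pre-SET (rested, the positive
class) or post-SET (fatigued).  The stages are: synthetic signal
generation → low-pass filtering → hoof-event detection → stride
windowing → 52 per-stride features → intra-individual normalization →
104-value horse-trial vectors → NCA ranking → greedy forward selection →
leave-one-subject-out (LOSO) classification, looped over three datasets
(all / high / low SET intensity), three gait subsets (walk, trot,
walk+trot), four variability metrics and five classifier families.

## Synthetic gait model

The generator produces the signal *content* the feature pipeline
measures, not a full equine kinematic simulation.

* **Channels.** Every displacement and angle trajectory is one or two
  stride-frequency harmonics, so accelerations (second derivatives) and
  angular velocities (first derivatives) are emitted in closed form.
  Trunk/poll vertical displacement is `A₂ sin(4πφ) + A₁ sin(2πφ)`
  (φ = stride phase); the amplitudes are solved numerically so that the
  range of motion and the difference between the two peaks (the MaxDiff
  symmetry index) hit their prescribed values exactly.  By the odd
  symmetry of this profile, ground-truth MinDiff equals MaxDiff.
* **Stance/swing.** Limb angles follow `(R/2)·sin(2πS(φ) + c)` where the
  swing-phase warp S accumulates a raised-cosine gate that is ≈0 during
  stance and ≈1 during swing (transition half-width 0.05 stride).  The
  limb gyroscope therefore nearly vanishes during stance — the signature
  the event detector keys on — and hoof-on/off are *defined* as the
  gate's falling/rising edge midpoints.  The three limb-channel phase
  constants (pro/ret 0, abd/add +π/2, int/ext −π/2) are chosen so the
  gyro magnitude never vanishes inside swing, and so the pro/ret channel
  is near an extremum at the stance edges, which keeps the transition
  shape clean for edge refinement.
* **Defaults.** Walk: stride 1.10 s, duty factor 0.62, speed 1.5 m/s;
  trot: 0.75 s, 0.42, 3.5 m/s.  Limb pro/ret ROM 55–70°, abd/add ≈ 9–12°,
  int/ext ≈ 7–9°, trunk angular ROM 4–12°, trunk vertical displacement
  ROM 0.045 m (walk) / 0.090 m (trot), limb longitudinal displacement
  0.85–1.0 m, peak asymmetry 6–10 mm.  These are plausible magnitudes
  for a sound sport horse chosen once; the pipeline only requires that
  they be recoverable, not physiologic in detail.
* **Speed tie.** The sacrum longitudinal oscillation ROM is coupled to
  speed as `ROM = 0.12 · speed · stride_duration`, so the displacement-
  based speed stand-in (below) is unbiased on synthetic data.
* **Fatigue effects** are multiplicative deltas applied pre→post to named
  parameters.  Defaults: walking stance +10%, trotting swing −8%,
  front-limb longitudinal displacement −12%, hind-limb pro/ret ROM −10%
  — the direction and rough size of the reported post-exercise changes.
  Stance/swing effects reshape the duty factor at fixed stride duration.
* **Variability.** Inter-horse baselines are perturbed multiplicatively
  (CV 8% by default), per-stride duration and amplitude jitter (CV 4%),
  and i.i.d. Gaussian sensor noise is added per sample (0.02 g, 2 deg/s).
  No gyro bias, accelerometer drift, soft-tissue artefact or gravity
  leakage is simulated: emitted accelerations are gravity-compensated
  linear accelerations.  Consequently, passing tests show the *pipeline*
  is correct and the *procedure* behaves as designed under controlled
  conditions; they do not show field robustness to mount slippage,
  orientation error or gravity-removal error in real recordings (a
  gravity-removal hook would be the first addition for real data).
* **Lactate.** Each horse belongs to a high- or low-intensity exercise
  group (44:16 ratio by default); maximum plasma lactate is drawn from
  N(4.04, 1.80²) or N(1.62, 0.57²) mmol/L respectively, matching the
  study population's group statistics.

## Preprocessing

* **Filter.** 4th-order Butterworth low-pass, 30 Hz cutoff, applied
  forward–backward (`sosfiltfilt`).  Zero-phase filtering doubles the
  effective order but leaves event timing unshifted, which matters
  because durations are features.  The effective squared magnitude
  response of the digital filter is `1/(1 + r⁸)` with
  `r = tan(πf/fs)/tan(πfc/fs)` (bilinear prewarping); tests use this
  closed form.
* **Hoof events.** Stance is where the smoothed (25 ms moving average)
  right-front gyro magnitude falls below θ = 0.15 times a sliding 95th-
  percentile level (window = 2 stride periods, period estimated from the
  autocorrelation).  Runs shorter than 0.15 period are discarded,
  sub-0.1-period gaps merged, and each edge is refined to the 50%-level
  crossing of the transition, matching the generator's event definition.
  Edges that never reach the 50% level (truncated boundary stances) are
  dropped.  At zero noise recovered hoof-ons land within one sample of
  ground truth; at gyro noise up to 5% of the swing amplitude ≥95% land
  within three samples.  The detector is a documented rule-based
  stand-in with a pluggable interface.
* **Windowing.** Strides are half-open sample intervals between
  consecutive hoof-ons, labeled with horse/trial/gait.  Strides whose
  duration deviates from the recording median by more than 3 scaled
  (×1.4826) median absolute deviations — floored at 2% of the median so
  sub-sample jitter cannot trigger mass-dropping — are discarded as
  missed-event guards.

## Feature extraction (52 per stride)

Durations come from the event times, with swing constructed as
stride − stance so the three are always consistent.  Angular ROMs
integrate the mean-free angular velocity per stride (trapezoidal) and
take max − min; limb ROMs use per-axis integration rather than a full
attitude-reference fusion, acceptable because only the per-stride range
is needed.  Displacements use cyclic double integration: convert g to
m/s², remove the stride mean, integrate, remove the drift line, integrate,
remove the drift line again.  The stride is treated as one period of a
cyclic signal — integration runs over the periodic extension (first
sample appended) and the drift lines connect true period endpoints,
which closes the displacement loop exactly and removes a systematic
bias (~2% in ROM, ~10% in MaxDiff) that plain endpoint detrending
leaves.  MaxDiff/MinDiff take the two most prominent circular peaks and
troughs (prominence ≥ 2% of the range to reject noise ripples); profiles
without two peaks yield a missing-value sentinel and the stride is
excluded from aggregation.  A flat profile is perfectly symmetric and
yields 0.  Speed is a documented stand-in for an external learned model:
`speed = (ROM_long_sacrum / 0.12 + offset) / stride_duration`, the 0.12
being the generator's oscillation-to-stride-length ratio; with the ratio
set to 1 this reduces to plain displacement over time, and the function
is pluggable for real data.

## Normalization, aggregation, selection, evaluation

Features are min–max scaled to [0, 1] per horse and per feature over the
pooled pre+post strides of the subset (constant features map to 0), then
summarized per horse-trial by the mean and one variability metric — RMS,
CV, SD (sample, n−1) or VAR — giving 104 values.  Horse-trials with
fewer than 33 strides are excluded (the stated validity floor;
configurable).  An optional sliding-window mode (33-stride windows,
step 1) mirrors per-stride sample counts but is off by default: the
classification unit is one vector per horse per trial.

NCA is the feature-weighting variant: per-feature weights, L-BFGS with
analytic gradient from the all-ones start, objective = mean leave-one-out
soft-neighbour probability of the correct class minus λΣw² (λ = 1/n by
default).  Features are ranked by |w| with ties broken by canonical
feature order.  Greedy forward selection evaluates LOSO accuracy on
ranking prefixes of size 1, 2, … and stops at the first *strict*
decrease (equal accuracy continues — which on perfectly separable
synthetic data lets the prefix grow to the full ranking).  Speed and the
gait-event durations are always computed and reported in a separate
pre/post comparison regardless of whether the ranking selects them; a
flag can force them into the classifier's feature set.

LOSO-CV holds out one horse (both trials) per fold; confusion counts are
pooled across folds, and per-fold metrics give the mean ± SD in the
report.  SVM is linear with C = 1 (features are already in [0, 1]); kNN
uses k = 5; tree, naive Bayes and logistic regression use library
defaults.  All hyperparameters live in the config.

Note a deliberate property of the prescribed procedure: feature ranking
is computed on the full subset *before* LOSO, so the selected model's
null accuracy is optimistically biased (≈0.6 rather than 0.5 on
label-independent data at 104 features).  The null-calibration
experiment documents this; moving selection inside the folds would
change the method being studied.

## Pipeline report

Datasets: `all`; `high`/`low` by applying the 4.0 mmol/L cutoff to each
exercise group's mean maximum lactate (group-level, because individual
horses in a high-intensity group can fall below the cutoff; boundary
value 4.0 → high).  The walk+trot subset uses the union of the same
horses' walk and trot strides.  For each of the nine cells the best
(variability metric, classifier) pair by pooled LOSO accuracy is
reported with the selected features, fold mean ± SD of
accuracy/sensitivity/specificity, confusion counts and stride counts;
non-evaluable cells are marked with a reason and the run continues.
Identical config and seed give identical report bytes.

## Problem sizes

The shipped experiments use 20-horse cohorts at 33–36 strides per trial
for recovery and classification checks, 40 horses for null calibration,
and 20 replicates for the selection-soundness rate; these sizes make the
full suite and the acceptance script run in a few minutes while keeping
every per-horse quantity above the 33-stride validity floor.

## Known limitations

* The generator's harmonic waveforms are a stand-in, not a claim about
  true equine IMU morphology; absolute feature values are only as
  realistic as the prescribed parameter magnitudes.
* The hoof-event detector and speed estimator replace external learned
  models and are validated only against the generator's definitions.
* No gravity removal, sensor-to-segment alignment or orientation fusion
  is implemented; real recordings would need those stages first.
* Binary fatigue only; graded fatigue levels and single-stride
  classification are out of scope.
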