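# Methods

This note documents the generative model behind the synthetic data, the
detector and its training, the kinematic and statistical procedures, and
the numerical choices a user should know before trusting or extending
the results.

## 1. Sensor-trial model

A grasp trial is 10 s of 10 voltage channels (force and flex per digit,
digit order thumb→little) sampled at 40 Hz (401 frames), clipped to
[0, 3.3] V.

**Hold trials.**  Each engaged channel follows a logistic rise → plateau
→ fall envelope (rise/fall midpoints at 1.8 s and 8.2 s, time constant
80 ms); the annotated hold window is the 5 s span from 2.5 s to 7.5 s,
which sits deep inside the plateau.  Nominal plateau levels are 2.0 V
(force) and 1.5 V (flex), scaled by per-digit engagement factors
(1.0, 1.0, 0.95, 0.90, 0.85).  Three multiplicative disturbances ride on
the plateau:

* a per-trial amplitude factor, 1 + N(0, 0.02), common to all channels
  (grip-strength variation between repetitions);
* a slow common-mode drift, ±1.5 % at 0.4–0.8 Hz (postural sway);
* for precision pinch only, anti-phase index/thumb load sharing: a
  saturated sine (tanh-shaped, amplitude 2.4 %) that trades force back
  and forth within the pair.  By construction the instantaneous pair
  mismatch never exceeds 5 %, yet the pair dwells near that bound —
  which is exactly the regime in which an instantaneous equilibrium test
  under-performs a per-channel band rule.

For tri-pod and whole-hand grips the thumb force plateau is scaled by
0.15 (weak pad opposition), which defeats any thumb-cancellation test on
those grips.

**Tap trials** replace the envelope with eight Gaussian contact bursts
(σ = 80 ms, < 0.5 s each, random amplitudes 0.5–1.0 of plateau); **rest
trials** are noise only, with a floor of 0.5 % of full scale.

**Noise** is additive Gaussian per channel with SD
`noise_sd × max(level_c / level_full, 0.25)`; the default
`noise_sd = 0.04 V` is 2 % of the full plateau.  Scaling the SD with the
channel's own engagement level keeps "2 % of plateau" true per channel,
so a weakly opposed thumb (0.3 V plateau) remains labelable within its
own ±10 % band; a flat-in-volts SD would swamp it.  The drift amplitudes,
frequencies and trial-gain SD above were set so that the generator's
stated contract holds at defaults: ≥ 90 % of hold-window frames label
secure, and the detector ordering described in section 3 below is
reproduced with margin across seeds.  They are conditions of the simulated study, not free parameters
of the analysis.

## 2. Labeling and splits

Hold statistics are pooled per grip over all of a subject's hold windows.
A frame is secure iff every *active* channel (hold mean ≥ 5 % of full
scale; configurable, 0 forces all channels) is within ±10 % of its mean.
Tap trials are labeled against their grip's statistics and rest trials
against the pinch statistics, so one rule labels the whole corpus and
everything outside the plateau band is insecure by the same arithmetic.

The default split is 70/15/15 at the *frame* level, seeded.  Frame-level
splitting leaks temporally correlated neighbours between splits; a
`by_trial=True` mode splits whole trials instead for honest
generalisation estimates.  The frame-level default matches the per-sample
split convention of the emulated protocol.

## 3. Detector training and the analytical baseline

The network is 10 inputs → 10 tanh units → 1 logistic output, inputs
affinely mapped per channel from the training-split min/max to [−1, 1].
The loss is mean binary cross-entropy in nats (outputs clamped at 1e−12
inside the logs for stability).  Training uses Møller's scaled conjugate
gradient: σ = 5e−5 (finite-difference step scale), initial λ = 5e−7,
weights initialised uniform in [−0.5, 0.5] from the training seed (a
1/√fan-in mode is available).  Weight updates occur only on iterations
whose comparison parameter is non-negative, so the training-CE trace is
non-increasing; λ-inflation steps leave the weights untouched.  Early
stopping: training halts after 6 consecutive validation-CE increases
(counted over weight-changing iterations) and the best-validation
weights are returned; cap 1000 iterations.  The per-iteration CE on all
three splits is stored in the model.

Rounding: ŷ > 0.5 ⇒ secure; exactly 0.5 maps to insecure, the
conservative choice for triggering feedback.

The analytical pinch rule returns secure iff thumb and index force both
exceed 10 % of full scale and agree within 10 % of the larger value.
Evaluation reports, per split: CE, percent error after rounding, and
mean squared error both of the continuous output and of the rounded
output; and per grip, the true-positive rate on secure test frames, with
the analytical rule scored on the same rows.  On default corpora the
learned detector's pinch TP exceeds the analytical rule's (the rule
trips over the near-bound load-sharing mismatch), and analytical-style
thresholding on tri-pod/whole-hand corpora is useless (TP ≈ 0 ≪ 50 %)
because the thumb never clears the floor.

## 4. Feedback scheduling

IBF delays are anchored at 1 s on trial 1 and 0 s on trial n, giving
delay(k) = (n − k)/(n − 1) and a per-trial decrement of 1/29 s ≈ 34.5 ms
for the standard 30-trial block (the 1/30 alternative would give
33.3 ms and a non-zero delay on the last trial).  Onset detection
returns the first frame opening a run of ≥ `debounce_frames` secure
rounded outputs (default 1; raise it if single-frame flicker matters).
Events are simulation-time records: a 100 ms beep at detection + delay
and an LED interval from beep onset to object release.  If the delayed
onset falls after release — possible early in the IBF ramp, where the
delay (1 s) is comparable to the task itself — the event is emitted with
an empty LED interval and flagged `led_truncated`; the emulated protocol
does not specify this case.

## 5. Trajectory model and kinematic metrics

A task trial moves the object-centre 0.20 m in the table plane with a
minimum-jerk profile s(u) = 10u³ − 15u⁴ + 6u⁵, a 2 cm lift bump and a
lateral bow, padded by 0.3 s of rest at both ends and sampled at 120 Hz.
Trial-to-trial variability is injected at the *metric* level: the
realised (T, P, E) triple is the learning-model expectation plus
Gaussian trial noise, and the geometry is then solved to realise it —
the end point is offset from the target by E, and the bow amplitude is
root-found (Brent, tolerance 1e−12 on a 2001-point trapezoidal arc
length) so the path's arc length equals P.  This makes the configured
trial SDs exact properties of the realised metrics and parameter
recovery well-defined; the cost is that individual trajectories are
smoother than motion-capture data (no waypoint jitter, no marker noise),
so the kinematic layer is exercised on clean curves only.

Metrics are computed after linear resampling onto a uniform 100 Hz grid
spanning the recording.  Speed is the central-difference velocity norm
(one-sided at the ends); the object "moves" where speed exceeds a gate
(default 0.01 m/s for measured data; 0 is the literal non-zero-velocity
rule for clean data, with speeds below 1e−9 m/s treated as rest because
interpolating a stationary segment leaves last-ulp position jitter).
Completion time is (moving samples) × 10 ms; pathlength sums
displacements between consecutive moving samples; placement error is
the in-plane distance between the trailing-rest mean position and the
target centre, both orthogonally projected onto the table plane.

Accuracy: pathlength and placement round-trip the configured values to
better than 0.1 % (placement exactly).  Completion time is widened by
the sampling chain — the ±10 ms central-difference window plus the
off-grid motion boundaries of 120 Hz data add one to roughly three
analysis samples — so scored T sits 0.01–0.03 s above the configured
duration, a constant offset that cancels in slopes and block
differences.  For trajectories whose motion boundaries lie on the
100 Hz grid the widening is exactly one sample.

## 6. Learning model of the study

Per subject, mode, metric, trial:

value = b·(baseline) + slope·(k − 1) [training] or + Δ [post] + ε

with b a per-subject log-scale-free baseline factor 1 + N(0, CV),
per-subject slope and Δ drawn around the mode's mean, and per-trial
noise ε.  Defaults (units: completion time s, pathlength m, placement
error m):

| quantity | time | path | placement |
| --- | --- | --- | --- |
| baseline mean | 1.48 | 0.25 | 0.0056 |
| baseline CV | 0.24 | 0.07 | 0.12 |
| trial SD | 0.13 | 0.010 | 0.0015 |
| slope NF / IF / IBF (per trial) | +0.0067 / −0.0023 / −0.0048 | +2.64e−4 / −1.15e−4 / −2.58e−4 | +2.4e−5 / −1.3e−5 / −8.6e−6 |
| slope SD (between subjects) | 0.0055 | 2.3e−4 | 9.1e−5 |
| post effect NF / IF / IBF | +0.0156 / −0.0831 / −0.090 | +0.0022 / −0.0017 / −0.0065 | +8.7e−4 / +1.8e−4 / +7.1e−5 |
| post effect SD | 0.126 | 0.0072 | 0.0015 |

Positive NF slopes encode mild fatigue decline without feedback;
negative IF/IBF slopes encode improvement.  Between-subject SDs were
chosen so the total outcome variability (trial-noise contribution plus
heterogeneity) matches the emulated cohort; with these defaults a
one-sample t-test on 17 IBF completion-time slopes rejects zero in
~85 % of replicated studies.  All randomness derives from one master
seed through `SeedSequence([seed, subject, session, block, trial])`, so
studies are reproducible element-wise and trajectory-backed and
metric-level generation realise identical values.

## 7. Statistics layer

Normalization divides all three blocks by the subject's pre-block mean
(the pre block included, so its normalized mean is exactly 1; the
emulated protocol only mandates normalizing training/post values —
toggleable via `normalize=False`).  Outcomes are reported in metric
units by multiplying by the raw group pre-training mean.  Δ is stored as
post − pre (negative = improvement); the pairwise block table prints
both orientations to avoid sign confusion.

Tests are computed from textbook sum-of-squares forms: one-factor
within-subject ANOVA (sphericity assumed, no Greenhouse–Geisser
correction), with pairwise block differences using the pooled RM error
term (SE = √(2·MS_err/n)) and Tukey-HSD p from the studentized-range
distribution; one-way between-groups ANOVA on outcomes with Tukey-Kramer
post hocs, optionally Bonferroni-scaled across metric families (default
family count 1, since the combination of Tukey and Bonferroni is
non-standard); classic pooled-variance t-tests.  p-values come from
scipy's F, t and studentized-range distributions; the test suite checks
all of these against statsmodels, pingouin and scipy reference
implementations on randomized designs.  Degenerate inputs (zero
between-level variance, zero error variance, zero sample variance) are
returned with explicit F/p conventions (F = 0, p = 1 when the effect sum
of squares is exactly zero) and flagged rather than raising.  Outcome
ANOVAs treat the three feedback modes as independent groups, mirroring
the emulated report; a repeated-measures treatment of the same subjects
across modes is available by passing the outcome table to `rm_anova`.

## 8. Problem sizes and limitations

The shipped tests and the acceptance script run one subject's full
corpus (125 trials, ~50k frames) for detector training, a 17-subject
trajectory-backed study (3060 trials) for the end-to-end pipeline, and
200 metric-level replicated studies for the power estimate; these sizes
keep a full run in tens of seconds while leaving every statistic at the
cohort size it emulates.

What passing tests do *not* show: the generator contains no sensor
drift between sessions, no marker dropout or soft-tissue artefact, no
failed or aborted trials, and its secure/insecure structure is exactly
the labeling rule's — so detector accuracies here are upper bounds, and
the analytical-vs-learned gap is far smaller than with real grasps.  The
statistics layer assumes the balanced design it is given and refuses
missing cells rather than imputing.
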