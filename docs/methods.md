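# Methods

This note documents the models, parameters and design choices behind
`tiltwalk`, and what the synthetic-data tests do and do not establish
about real recordings.

## The measurement problem

Blindfolded subjects walk "straight ahead" for 2 minutes after a
5-minute adaptation period in one of four conditions (baseline sitting,
supine, right-ear-down, left-ear-down). Because the hall is finite, the
walk is split by experimenter-imposed turns into walking segments (WS).
Two independent sensor systems record the walk: body-worn inertial
trackers (chest + both ankles used here) and pressure-sensing shoe
insoles with embedded IMUs, each sampling at 100 Hz on its own clock.
The analysis asks whether the preceding roll-tilt biases heading
(trunk yaw drift) and lateral weight distribution (left–right CoP
asymmetry), and whether the two measures co-vary.

## Pipeline

### Synchronization and gap repair

The subject slaps their legs together before walking; the slap appears
as a dominant transient in the medio-lateral acceleration of the left
ankle tracker and the left insole. `detect_slap` takes the largest
absolute-acceleration peak above a threshold inside a search window
(default: first 15 s). The default threshold is 10× the median absolute
deviation of the windowed signal — robust, scale-free, and far below the
slap, which is by protocol an order of magnitude above walking
accelerations. Ties are impossible by construction (global maximum
wins). The insole clock is then shifted by the difference of the two
slap times; values are never resampled, and no clock-skew (drift)
correction is attempted — downstream event detection runs per system
precisely so that residual inter-system drift is harmless.

Missing samples are repaired by modified-Akima (makima) piecewise-cubic
interpolation, but only for gaps ≤ 0.2 s (default `max_gap_s`); longer
gaps and gaps touching a trace boundary are left missing and reported.
Interpolating across longer gaps would fabricate gait structure.
Observed samples are never modified.

### Gait events

Events are read from the sagittal-plane angular velocity of each ankle
after zero-phase (forward–backward) 4th-order Butterworth low-pass
filtering at 12 Hz. Zero-phase filtering matters: event *timestamps*
must not lag the raw signal. Per stride:

* mid-swing — positive peak above an adaptive threshold of
  0.4 × the 95th percentile of the signal's positive part (a scale-free
  stand-in for per-trial manual thresholds), with a minimum peak
  separation of 0.4 s (cadence is physiologically < 2.5 strides/s/foot);
* toe-off — minimum in the window from the previous mid-swing (capped
  at 0.8 s back) to the current mid-swing;
* heel strike — the datapoint at the first positive-to-nonpositive
  zero-crossing after the peak. The crossing is located by linear
  interpolation between the bracketing samples and the nearer sample is
  reported, so the index is unbiased rather than systematically one
  sample late.

Strides whose toe-off window is empty or that never cross zero are
dropped and logged. Both feet's strides are merged and split into WS
wherever consecutive mid-swing times differ by ≥ 2 s; segments with
fewer than 3 strides are discarded (the first/last steps around a turn
are too variable to support a regression), and the survivors are
renumbered WS1, WS2, … in temporal order.

### Orientation and yaw slope

Orientation is estimated from the chest gyroscope and accelerometer
only — no magnetometer, since indoor magnetic fields are unusable and
only heading *change* within a WS matters. The filter integrates body
rates through exact intrinsic yaw–pitch–roll (ZYX) Euler kinematics and
pulls pitch and roll toward the accelerometer's gravity direction with a
first-order complementary gain. The correction acts on the tilt angles
only; yaw is pure gyro integration from an identity start (sensors are
reset in neutral standing pose). This is deliberately not a literal
Kalman filter: the only property the analysis relies on is the
tilt-correction contract, which this structure makes explicit and
testable. Axis convention: body z cranio-caudal, x anterior, y left;
positive yaw = leftward chest rotation. Walking keeps pitch far from
±90°, so gimbal lock is treated as an error, not handled.

The tilt time constant defaults to 1.0 s. A slower constant (several
seconds) leaks less transient linear acceleration into tilt but
converges too slowly from a cold start — with 1.0 s a 30° static tilt is
recovered to well under half a degree within 5 s, while the effect of
accelerometer noise on *yaw* is exactly zero by construction, which is
the quantity this pipeline regresses.

Per WS, unwrapped yaw (±180° jumps removed; regressions across
wrap-arounds are meaningless) is regressed on time by ordinary least
squares over *all* samples of the segment, not per-stride means: the
step-locked twist oscillation visible in raw yaw largely averages out
over whole strides, and its residual contribution is part of the
measurement noise. The slope (deg/s) is the heading measure.

### Centre of pressure

The CoP of a pressure frame is the pressure-weighted centroid of the 16
sensor positions (modelled as a 4×4 grid of cell centres spanning the
normalized −0.5…0.5 insole plane; the vendor documents the sensor count
but not the geometry). The two devices' lateral axes point in opposite
anatomical directions, so the right insole's lateral axis is mirrored at
load time; afterwards y is positive toward medial on both feet and

    CoP_LM_Sym = CoP_LM_left − CoP_LM_right

is a pure left-minus-right contrast: negative = disequilibrium to the
left. Stance is defined as same-foot heel strike to the subsequent
same-foot toe-off; samples count as loaded above a contact threshold of
5% of the trial's 95th-percentile total force. Within a step the CoP is
averaged force-weighted; across the steps of a WS, unweighted — matching
the two-stage "per step, then per WS" averaging of the protocol. A WS
with no valid step on one foot yields a missing symmetry value and the
trial drops out of CoP analyses only.

### Study-level inference

Analysis uses the first three WS of each trial (later segments exist in
fewer trials). Within each condition × WS cell, points farther than
3×IQR beyond the quartiles are removed once; boundary-exact points are
retained, and a degenerate cell (IQR = 0) is passed through unchanged.
This single-pass rule is *not* idempotent on adversarial inputs (heavy
mass at a quartile can make fences shrink after removal); it is applied
once by definition.

The mixed model is

    value ~ trial + walkingSegment + trial:walkingSegment
            + (1 | participant) + (1 | participant:walkingSegment)

fit by REML (statsmodels `MixedLM`; random intercept per participant
plus a WS-within-participant variance component, because any decay of a
condition effect takes an individual course). The interaction is
included because condition effects shrink over successive WS. Estimated
marginal means per condition × WS come from the fixed-effect design;
all 6 pairwise condition contrasts per WS are tested against the
studentized-range distribution (Tukey family, k = 4). Degrees of
freedom use the containment-style residual count
(n_obs − n_fixed_params); the method is recorded in every report. With
~900 observations the df choice is immaterial, and the inference surface
is calibrated by simulation (power and null rejection rates), not by
exactness of any single p-value. Significance stars use 0.05/0.01/0.001.
Singular fits (a variance component estimated at ~0) are flagged, not
failed.

Assumption checks (Bartlett, Levene, Shapiro–Wilk per condition) are
reported but never branch the analysis.

For the yaw–CoP correlation, each subject's repetitions at WS1 are
averaged per condition, the subject's baseline average is subtracted,
and the resulting 3 points per subject (supine, RED, LED) for both
measures enter a Pearson correlation. Averaging precedes baseline
subtraction; subjects without baseline data are excluded and logged.

## The synthetic-data generator

`synthgait` emulates the measurement setup with analytically placed
features, so generated trials carry exact ground truth.

* **Stride waveform.** Sagittal ankle angular velocity is a sum of
  half-sine lobes per stride of period T = 1/cadence: toe-off valley
  (depth 0.5 A, minimum at 0.12 T), mid-swing peak (A = 200 deg/s at
  0.32 T), heel-strike zero-crossing at 0.42 T, and a shallower
  post-heel-strike valley whose entry slope matches the mid-swing lobe's
  exit slope, making the crossing locally odd-symmetric so zero-phase
  filtering does not displace it. Default cadence 0.9 strides/s/foot —
  a convention for slow comfortable walking, not a measured value.
* **Chest signals.** Within a segment, yaw advances at a constant drift
  rate plus a twist oscillation `amp·(cos(2πk(t−t0)/d) − 1)` with an
  integer number of cycles k per segment. The cosine phase makes the
  oscillation orthogonal to a linear trend, so the continuous-time OLS
  slope equals the injected rate exactly, and trapezoid-integrating the
  yaw-rate channel over a segment recovers it to machine precision
  (segment boundaries are snapped to the sample grid). The
  accelerometer reads gravity rotated by the instantaneous orientation
  plus white noise; no linear walking acceleration is simulated, since
  the pipeline uses the accelerometer only for tilt.
* **Conditions.** Default drift rates {baseline +0.1, supine +0.2,
  RED −0.4, LED +0.6} deg/s reproduce the qualitative ordering
  LED > supine > baseline > RED with a small overall leftward bias;
  CoP symmetry offsets {0, 0, +0.05, −0.05} oppose the drift in sign,
  so yaw and CoP measures correlate negatively by construction. An
  optional exponential drift decay across the walk is off by default
  (the decay's functional form is not established; within a segment the
  rate is constant either way so ground truth stays exact).
* **Insoles.** During stance the target CoP ramps heel→toe in x with a
  constant lateral offset (±half the injected symmetry per foot, the
  right foot written in its mirrored device frame); total force is a
  half-sine bump, and force is distributed over the 4×4 grid by bilinear
  weights so the frame centroid equals the target exactly. Sensor noise
  is added and clipped at zero.
* **Synchronization and dropouts.** A 3-sample slap impulse at 10× the
  walking ML-acceleration amplitude is written to the left ankle and
  left insole; the insole clock can be offset to exercise
  synchronization. Missing-sample gaps can be injected at configured
  times.
* **Studies.** `simulate_study` draws one persistent heading bias per
  subject (SD 0.3 deg/s by default) added to all conditions, runs
  baseline first and the adaptation conditions in per-subject random
  order, 3 repetitions each, 25 subjects — the repeated-measures design
  of the experiment. Everything is a pure function of the seed.
* **Measure-level simulation.** `simulate_measure_table` and
  `simulate_paired_measure_tables` generate study tables directly
  (condition effect × WS decay + subject intercept + noise) for
  calibrating the inference at hundreds of replicate studies without
  re-synthesizing 100 Hz traces; defaults (25 subjects × 3 reps,
  subject SD 0.2, residual SD 0.2, WS decay 1.0/0.6/0.36) mirror the
  study design and effect magnitudes above.

### What passing tests show — and what they don't

Parameter recovery on these synthetics verifies the *pipeline logic*:
event rules, segment separation, the sign conventions, the fusion
contract, the two-stage CoP averaging, the model structure and its
calibration. The generator deliberately omits several features of real
data: soft-tissue and footwear artefacts, stride-to-stride timing and
amplitude variability, turning kinematics during gaps (signals are
simply quiet), inter-system clock *drift* (only a fixed offset),
insole temperature drift, and magnetic or linear-acceleration
disturbances of the chest IMU. Accuracy numbers reported by the tests
are therefore upper bounds for real recordings, not estimates of field
performance.

## Numerical choices and degenerate inputs

* Sample indices are 0-based; windows half-open; event times in seconds
  on the trace clock; angles in degrees throughout.
* Clock shifts accumulate against the raw timestamps so applying the
  negative offset restores the original clock bit-for-bit.
* Filtering requires the signal to exceed the filtfilt warm-up length;
  shorter signals are an error, as are sample rates below twice the
  cut-off.
* All-zero pressure frames (swing) have undefined CoP and are excluded
  by the contact threshold; a single-step WS reports SD 0 by convention.
* Zero-norm accelerometer samples skip the tilt correction (gyro-only
  step); NaN gyro samples integrate as zero rate.
* Problem sizes in the test suite and acceptance script (e.g. 40–60 s
  walks, 2–3 segments, tens of replicate studies for recovery grids,
  100/200 replicates for power/null calibration) are chosen to exercise
  every code path at desk scale while keeping the full run in minutes.

## Known limitations

* No path integration: veering is quantified indirectly via yaw slope
  and CoP asymmetry; absolute trajectories are not reconstructed.
* The Tukey p-values use a residual-df approximation rather than
  Satterthwaite/Kenward–Roger; fine at this design's size, but small
  studies would warrant a finer df method.
* The CoP sensor geometry is a modelling convention; absolute CoP
  values in real data are hardware- and fit-dependent and should be
  interpreted only relative to baseline, which is what the analysis
  does.
* Only a constant inter-system clock offset is corrected; slow relative
  drift between systems is mitigated by per-system event detection, not
  estimated.
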