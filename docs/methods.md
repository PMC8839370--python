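# Methods

This note records the models, parameter choices and numerical decisions
behind `gaitreliab`, and what the synthetic-data validation does and does
not establish.

## Measurement model

Each assessment is a two-minute self-paced walk recorded by three 6-channel
IMUs (3-axis accelerometer, m/s²; 3-axis gyroscope, deg/s) at 104 Hz: one on
each foot and one on the low back at L5/S1, with five-second standstills
before and after the walk. Accelerometers report specific force (a
stationary sensor reads +1 g upward). Gyroscope bias is estimated as the
per-axis mean of a separate stationary recording and subtracted during
preprocessing; a motion check (per-axis SD below 2 deg/s) guards the
calibration.

## Preprocessing

Fixed order: (1) polyphase rational resampling to 100 Hz (25/26 for 104-Hz
input) — antialiased and deterministic; (2) gyro-bias subtraction; (3) the
first and last two seconds dropped (transitional movement); (4) walking
bounds from the leading/trailing runs of "stationary" samples, where a
sample is stationary when both the smoothed |‖accel‖ − g| and the smoothed
gyroscope magnitude fall below their whole-signal means (smoothing window
0.25 s; runs must last ≥ 0.5 s; absolute floors of 0.02 m/s² and 0.02 deg/s
keep near-constant signals classified as stationary despite resampling
ripple). The assessment's combined walking span is the union of the
per-sensor spans — the assessment is "walking" whenever any sensor moves.
(5) A measurement is excluded when any sensor's residual walking duration
deviates *strictly more than* ten seconds from the expected duration.

## Orientation and ZUPT

Attitude is tracked by a gradient-descent accelerometer/gyroscope fusion
filter (gain β = 0.1) initialised from the mean gravity direction over the
first second, which must be quasi-static (mean gyro norm < 5 deg/s).
Acceleration is rotated to the earth frame and gravity subtracted. Axis
relabelling: VT is earth-up; the AP line is the first principal axis of the
horizontal gravity-free acceleration over the walking span; its sign comes
from the initial mounting pose whenever the pose projects usably onto that
axis (the sensors are mounted roughly anatomically), and from the direction
of net progression otherwise. Integrated accelerometer noise random-walks at
roughly 0.2 m/s over two minutes, so progression alone is an unreliable sign
oracle for sensors without net displacement (the lumbar sensor); the
pose-first rule makes the choice deterministic. ML completes the
right-handed frame (ML = VT × AP).

Stride displacement: gravity-free acceleration is integrated between
consecutive stance midpoints; velocity is linearly de-drifted so it is
exactly zero at both anchors (a zero-velocity update; constant acceleration
offsets are absorbed exactly); a second integration gives displacement, and
stride length is its horizontal norm. Bias-induced length error is bounded
by b·T²/4 per stride for a residual acceleration bias b over stride time T.

## Stride detection

All thresholds are computed over the walking span only — including the
standstill bookends would depress them.

- Stride-time prior: dominant frequency of the mean-removed ML acceleration
  in 0.2–2.5 Hz. A Welch periodogram (10-s segments) supplies the flatness
  guard (dominant peak ≥ 3 × in-band median, otherwise a prior-estimation
  error); the location is refined on a zero-padded FFT so stride-time
  resolution is a few milliseconds. Prior clipped to 0.4–5 s.
- Foot contacts: vertical-acceleration peaks with minimum distance
  0.75 × stride time and minimum height mean + SD.
- False negatives: every inter-contact gap > 1.5 × stride time is
  re-searched once with the height threshold scaled by 0.75. The re-search
  runs only over the sub-segment at least one minimum-distance away from
  both bounding contacts: a peak outside that region could never be kept,
  and must not shadow a valid peak during distance pruning.
- Stance: the longest span ≥ 0.2 s below both the acceleration
  (mean + SD of the gravity-free magnitude) and gyroscope (mean magnitude —
  deliberately asymmetric, following the rule as printed) thresholds between
  consecutive contacts, anchored to start at the leading contact so stance
  and swing tile the detected span. If a gap has no qualifying span, the
  lower of its two bounding peaks is removed (false-positive pass) and
  segmentation restarts; exhaustion raises a detection failure. Magnitudes
  are vector norms.

## Low-back events

The lumbar AP acceleration is integrated once (cumulative trapezoid) and
band-pass filtered with a second-order Butterworth, 0.25–15 Hz, applied as a
single zero-phase forward–backward pass — "filtered twice" read as the two
passes of zero-phase filtering. (The alternate reading, integrate-and-filter
twice, is available via `lowback_ap_mode="integrate_twice"`; double
integration yields a position-like series whose peaks are less suited to
contact detection, hence the default.) The first contact is the first
qualifying AP peak (same distance/height rule); the stepping foot is the
sign of the mean ML acceleration over the following half stride (right foot
positive by default, configurable). Remaining contacts are predicted by
accumulating the corresponding foot's inter-contact intervals *from the
anchor* — not from the previous snap, so one snap onto a noise maximum
cannot re-centre the whole tail — and snapped to the highest local AP
maximum within ±25% of the interval; failures are logged as missing, and
the other foot is anchored by a windowed peak search between the first two
contacts of the first foot.

## The feature catalogue

The catalogue is a versioned manifest of 166 uniquely named features:
56 spatio-temporal, 26 frequency, 63 complexity and 14 asymmetry, plus 7
low-back signal-magnitude features (RMS and peak-to-peak range per axis and
overall RMS) that close the total at 166 — the four named domains sum to
159, and the per-sensor arithmetic (46 left foot + 46 right foot + 54 low
back) leaves 20 combined features of which 14 are asymmetry; the remaining
slots are allocated to six combined spatio-temporal features (gait speed and
bilateral means) and the signal-magnitude block. Each entry carries domain,
source sensor, units and normalisation. The manifest ships as JSON and is
rebuilt programmatically; a test keeps the two identical.

- Spatio-temporal: per foot, stride/stance/swing/step time, stride length
  and velocity — each as the mean of per-10-stride-block statistics (mean,
  SD, CV; the final partial block is dropped and logged) — plus cadence and
  height-normalised length and velocity. Low back: stride and step timing
  from the matched lumbar contacts. Combined: gait speed, bilateral means,
  double-support time.
- Frequency: Welch periodograms (10-s Hann segments) over the walking span
  (minimum 30 s). Dominant frequency (parabolic sub-bin interpolation),
  dominant amplitude (power of the descending peak region), width (smallest
  greedy span around the peak holding 50% of in-band power), density (peak
  region power / in-band power); low back additionally an index of
  harmonicity (power at the dominant frequency over its first six
  harmonics) and a harmonic ratio (even over odd harmonics of the stride
  frequency; ML uses the same ratio, where stride-frequency harmonics are
  the relevant comb).
- Complexity: computed on exactly the first 25 strides, each axis
  time-normalised to 100 samples per stride (the low back is anchored to
  the left-foot cycle; its own event detection is less dependable and the
  cycle timing is shared). Sample and approximate entropy (m = 2,
  r = 0.2 × SD, Chebyshev distance; vectorised with naive O(N²) reference
  implementations used as test oracles); unbiased autocovariance and
  autocorrelation at one-stride and one-step lags; largest Lyapunov
  exponent by the divergence-curve method (embedding dimension 5, delay
  ¼ stride, Theiler window one stride, least-squares slope over the first
  half stride, reported per stride). Fewer than 25 strides yields missing
  values with reason codes, never an exception.
- Asymmetry: for swing time, stance time, stride time, step time, stride
  length, stride velocity and the swing/stance ratio — symmetry index
  SI = |P − NP| / (0.5(P + NP)) × 100 and ratio P/NP, with P the paretic
  side and the left foot as reference when the paretic side is unknown or
  both sides are affected.

## Reliability statistics

ICC(2,1): two-way random effects, absolute agreement, single measurement,
from the mean squares of the subjects × sessions table; 95% CI by the
McGraw & Wong F-distribution method with Satterthwaite degrees of freedom.
At least three complete subject pairs are required; incomplete pairs are
removed listwise per feature, and features observed in fewer than half the
subjects are flagged. SEM = SD_pooled·√(1 − ICC) with SD_pooled the ddof-1
SD of all test and retest observations concatenated; MDC = 1.96·√2·SEM;
rMDC = MDC / SD_pooled. Negative ICC estimates are reported as-is, classed
"poor", with SEM-derived statistics suppressed. Classification bands are
lower-inclusive: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
≥ 0.9 excellent.

## The synthetic-gait generator

The generator is the package's study-condition stand-in for clinical
recordings. Defaults: 120-s assessments at 104 Hz with 5-s standstill
bookends; 1.2-s strides (CV 3%), stance fraction 0.6, 1.30-m stride length;
30 m/s² impact transients (one 50-ms sine period peaking at the contact);
±200 deg/s biphasic swing pitch bursts that integrate to zero per stride;
0.04-m swing foot lift; continuous ML sway at stride frequency (1 m/s²);
lumbar AP velocity bumps of 0.4 m/s peaking at each step, VT oscillation at
step frequency, an ML component whose sign alternates with the stepping
foot, and a small trunk-yaw gyro oscillation; white noise of 0.3 m/s² and
1 deg/s; configurable gyro bias and mounting yaw.

Foot streams come from a consistent rigid-body model: world-frame forward
(raised-cosine velocity bump integrating to the stride length), vertical and
lateral accelerations plus a pitch trajectory are prescribed, and the sensor
stream is the specific force and angular rate expressed in the (optionally
yawed) sensor frame. Gravity removal and ZUPT therefore *recover* the stride
length rather than being fed it. The right contact is phase-locked within
the left cycle — its offset jitters around the step split (set by
`step_time_ratio`, the temporal-asymmetry control) without random-walking,
as alternating feet physically require. Per-foot stride-time pairs are
accepted but validated to imply equal stride counts ±1.

What the generator does *not* emulate: turns around cones (a flag exists but
turn segments are not implemented), walking-aid artefacts, soft-tissue and
clothing noise at the lumbar sensor, ground-contact transients at the low
back, foot-drop or spastic morphology changes, net lumbar translation along
the path, and magnetometer effects (the hardware has none). Passing the
synthetic validation therefore demonstrates algorithmic correctness under
the stated signal model — quasi-periodic impacts, quiescent stance, burst
swing, lumbar step periodicity — not clinical validity on real stroke gait.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` measure, against ground truth:
contact precision/recall at 50-ms tolerance over 100 seeded walks spanning
stride times 0.9–2.5 s, step-time ratios 1.0–1.4 and accelerometer noise
0.05–0.1 g (two-minute walks in the acceptance script; one-minute walks in
the test suite, which exercises the identical code path at a smaller problem
size); recovery of impacts attenuated to just below the detection threshold
(default-condition walks; the attenuation is applied in two passes because
removing peaks itself lowers the mean + SD threshold); ZUPT error on
noise-free trapezoidal-velocity trajectories of known length; ICC(2,1)
agreement with independent variance-components oracles; mean ICC recovery
at analytic levels 0.3/0.5/0.8/0.95 (n = 29, two sessions, 200 replicates);
the fixed 25-stride complexity window; and entropy agreement with the naive
references on 300-sample fixtures.

## Known limitations

- The stride detector assumes at least intermittent stance quiescence;
  continuous-motion signals (severe shuffling) raise a detection failure
  rather than guessing.
- Lumbar-only assessments have no spatial features; stride length requires
  the foot sensors.
- Without a magnetometer, heading is unobservable up to yaw drift; all
  horizontal quantities are defined relative to the walking direction.
- The harmonic-ratio and index-of-harmonicity definitions follow common
  trunk-accelerometry practice; other definitions exist in the literature.
- MDC uses the conventional 1.96·√2 factor; at ICC = 0.5 and SD = 2 this
  gives MDC = 3.92 exactly.
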