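# Methods

## Problem and measurement model

A smartphone rides in a pants pocket while a person walks 10 m, turns 180°,
and walks 10 m back. The phone's IMU samples 3-axis specific force (m/s²)
and angular rate (rad/s) at a nominal 100 Hz in the *device* frame, whose
orientation relative to the world is arbitrary and unknown but roughly
constant within a trial. The measurands are per-trial stride time (s),
stride-time variability (CV, %) and their dual-task costs (%). Because
stride time is a *timing* quantity, every processing choice below is made
to avoid biasing event times.

## Orientation and gravity

When a recording carries attitude quaternions (scalar-first, device→Earth)
they are used as-is. Otherwise attitude is estimated with a tilt-only
complementary filter operating on the gravity direction in the device
frame: the accelerometer, low-passed at 0.25 Hz (well below the ~0.9 Hz
stride frequency), provides the slow gravity reference; between updates the
direction is propagated with the gyroscope (dĝ/dt = −ω×ĝ), and the two are
fused with per-sample gain 2π·0.25·Δt. The per-sample rotation is the
shortest arc taking ĝ to Earth +Z. Yaw is deliberately left arbitrary:
downstream stages consume only the vertical acceleration and the vertical
angular rate, both invariant to yaw, so neither gyro-yaw integration drift
nor the compass matters (the heading column is accepted on file read but
not consumed).

Gravity is removed as a scalar: g is estimated as the median norm of the
0.25 Hz-low-passed rotated acceleration (default; a fixed value can be
configured) and subtracted from the Z channel. This matches the
"approximately vertical" frame contract and avoids coupling accelerometer
noise into a per-sample gravity vector.

Signals are resampled to a uniform rate (the nominal 100 Hz) by linear
interpolation before filtering, since the zero-phase filter assumes uniform
sampling. Sampling gaps >5% are flagged, not rejected.

## Filtering

All six channels are filtered with a 4th-order Butterworth low-pass at
3 Hz applied forward-backward (`sosfiltfilt`). The order is a design
choice (the gait literature uses 2nd–4th); 4th order was chosen for a
sharper stop-band while the forward-backward pass squares the magnitude
response and cancels phase, so detected trough times are not lag-shifted.
The effective gain is 1/(1+(f/3 Hz)⁸)² per the analytic response, verified
in tests at ten frequencies.

## Turn detection and straight segments

The yaw angle is the cumulative trapezoid of the *unfiltered* Earth-frame
vertical rate (the 3 Hz filter would smear turn edges). Any 4 s window
accumulating ≥120° flags a turn; 120° < 180° tolerates imperfect turns.
Flagged spans closer than 0.5 s are merged, then trimmed to where the
0.3 s-smoothed |yaw rate| exceeds max(15°/s, 20% of the span's peak rate),
which localises edges to within the turn's ramps. Straight segments are the
trial span minus turns dilated by a 0.5 s margin; segments shorter than 3 s
are dropped, and events within 0.5 s of a segment edge are discarded
because gait entering/leaving a turn is unsteady. The margin values are
design choices — the protocol specifies removal, not margins.

## Event detection

Within a segment, local maxima of the filtered vertical acceleration are
taken with a minimum spacing of 0.35 s (above the physiological step-rate
limit) and minimum prominence of 0.3× the local (4 s rolling) inter-quartile
range of the signal — a scale-free floor that adapts to amplitude damping
near turns. Each peak is scored by its amplitude minus the median of its up
to four surrounding peaks; since strict high/low alternation leaves only
two possible labelings per segment, the labeling maximising the total
signed score is selected. The heel strike of the phone-side leg is the
minimum sample between each HIGH peak and the next peak, refined to
sub-sample precision by parabolic interpolation; toe-offs follow LOW peaks
identically. If every segment yields fewer than 4 peaks the trial errors
out as insufficient gait.

Stride times are heel-strike differences within a segment only, gated to
the physiological range 0.3–3 s (violations dropped and flagged). The
summary uses the sample (n−1) SD — material at ~10–15 strides per trial —
and CV = 100·SD/mean. Per-participant values average the two assessments;
the aggregated dual-task cost is the mean of per-trial costs, not the cost
of averaged metrics (the two differ because the cost is a ratio).

## Synthetic walking trials

The simulator emulates the study protocol so the pipeline can be validated
without real data, with the generator's ground truth playing the role of a
gold-standard reference system. Stride durations are i.i.d.
Normal(mean, cv·mean) truncated at ±3 SD (truncation keeps the phase clock
monotone); a phase clock advances 2π per stride; the Earth-frame vertical
acceleration is A·[cos 2φ + a·cos φ] with base amplitude A = 2.5 m/s² and
step asymmetry a = 0.35, giving two peaks per stride of amplitude A(1+a)
and A(1−a) — the alternating high/low pattern of a pocket phone. The
waveform's troughs are closed-form (cos φ = −a/4), so heel strikes
(φ = arccos(−a/4) after each high peak) and toe-offs are *analytic*, never
detected — no circularity between simulator and detector. Published
ground-truth stride times are the differences of these analytic heel-strike
times. Anterior-posterior and medio-lateral channels carry smaller
harmonics at step and stride frequency; the turn is constant-rate yaw with
0.3 s cosine ramps integrating exactly to 180°, with gait amplitude damped
50% during the turn. White Gaussian noise (SD 0.15 m/s² on acceleration,
one tenth of that in rad/s on the gyro — consumer-MEMS-typical) is added in
the Earth frame, gravity (9.81 m/s²) is added to the vertical, and every
sample is rotated into the device frame by the inverse of a fixed random
unit quaternion (the pocket orientation).

Cohort defaults are the study-typical values: stride time 1.09 s (SD 0.08
across participants) single task and +0.08 s (SD 0.089) under dual task;
stride-time CVs of 3% (single) and 5% (dual) with 1/1.5 percentage-point
between-participant spread. Walking speed is tied to an assumed ~1.2 m
stride length so trials span the 10 m legs in ~9 s. The published cohort
variability magnitudes (40%/63%) are internally inconsistent with the CV
definition (they would imply stride-time SDs of ~0.44 s against a reported
SD of 0.08 s) and are not used; physiological CVs are. A latent severity
factor drives the true CV directly and each clinical score (UPDRS III,
MoCA with negative loading, HAM-A, HAM-D) with a configurable standardized
loading; covariates follow the cohort distributions (age 63±10 clipped to
40–83, 37% female, education 11±3 years).

**What the simulator does not emulate:** phone wobble inside the pocket
(orientation is fixed within a trial), accelerometer bias/drift and
temperature effects, festination or freezing-of-gait episodes, asymmetric
or shuffling waveform morphologies, stopping mid-trial, and timestamp
jitter. Passing validity tests therefore demonstrates correctness of the
signal-processing chain under the protocol's geometry and realistic noise,
not clinical performance on pathological gait.

## Validity evaluation

Reference metrics are computed from the true heel strikes restricted to the
same straight-walking windows the pipeline analysed (same turn dilation and
edge trim), mirroring a validation design in which both measurement systems
analyse the same straight-line walking; segmentation quality itself is
tested separately (turn edges within ±0.3 s, no events inside dilated
turns). The acceptance run uses 52 participants × 2 conditions × 2 trials;
event-detection sensitivity/precision are measured over 200 trials spanning
stride time 0.9–1.4 s and CV 1–10% at ±50 ms matching tolerance.

## Statistics

`validity` wraps the two-sided Pearson correlation plus mean/SD absolute
difference. The condition effect is modelled as a one-factor ANCOVA on
stacked participant-condition rows (`metric ~ condition + age + sex +
education`, type-II F for condition): the rows are treated as independent,
a documented simplification that ignores the within-participant pairing.
Clinical associations fit `z(score) ~ z(metric) + age + sex + education`;
z-scoring the outcome and the metric (covariates raw) defines the reported
standardized β. No multiple-testing correction is applied. Because the
regressor is the *measured* CV, its within-trial sampling error attenuates
recovered loadings by roughly var(true)/var(measured) ≈ 0.75–0.85 at
10–15 strides per trial — visible in the parameter-recovery tests, which
recover a 0.4 loading as ≈0.3–0.35.

Degrees of freedom are reported as computed from the fitted design
(condition F on 1 and n−4 when both conditions are present once per
participant); published df of the form (1, 103) for 52 participants × 2
conditions cannot be reconciled with a 4-parameter adjusted model and are
not reproduced.

## Problem sizes and determinism

Default problem sizes: 52-participant cohorts (two trials per condition)
for validity runs, 20 replicate cohorts for power/recovery checks, 200
trials for the detection sweep. All randomness flows from
`numpy.random.SeedSequence` spawning, so every simulation, test and the
acceptance script are bit-reproducible given a seed. Trial files round-trip
losslessly (17-significant-digit CSV, `float_precision="round_trip"` on
read).
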