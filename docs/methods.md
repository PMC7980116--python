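# Methods

## Measurement model

The package treats a waist-worn phone as a two-vector attitude sensor.  At
each 20-ms sample the gravity channel gives a "down" reference and the
magnetometer a "north" reference, both in device coordinates; the
device-to-world rotation matrix follows from the normalized triad
`A = g/|g|`, `H = (m × g)/|m × g|`, `M = A × H`, `R = [H; M; A]`, whose
rows are the world East, North and Up directions in device coordinates.
This is the standard gravity/magnetometer construction (the semantics of
the Android `getRotationMatrix` call whose output the recording app
stores), and it is the only attitude estimator used: no gyroscope
integration, no complementary/Kalman filtering, no calibration or low-pass
filtering, because the measurement protocol applies none.  "North" is
magnetic north; no declination correction is applied, which is irrelevant
to the statistics since a fixed heading offset cancels in the first
difference.

The triad is undefined when gravity and the field are near-parallel.  A
sample is rejected when `|m × g| < 0.1·|m|·|g|` (relative sine of the
angle between the references, mirroring the platform's failure condition;
configurable).  Rejected samples are dropped and counted, never
zero-filled, so a corrupted row cannot masquerade as a real orientation.

## Angle convention

Angles are ZYX (Tait–Bryan) with `R = Rz(θz)·Ry(θy)·Rx(θx)`:

- `θx = atan2(R32, R33)` — body right(−)/left(+) motion,
- `θy = atan2(−R31, √(R32²+R33²))` — up(−)/down(+), range [−π/2, π/2],
- `θz = atan2(R21, R11)` — forward(+)/backward(−) and heading.

This is the canonical "Euler angles from a rotation matrix" extraction and
the one consistent with naming the three outputs an x-, y- and z-axis
rotation.  At gimbal lock (|R31| ≥ 1 − 1e-9, i.e. θy within ~4·10⁻⁵ rad
of ±π/2) only θx ∓ θz is determined; the free angle is assigned wholly to
θx and θz is set to 0, a defined choice that still reconstructs the input
matrix exactly.  Locked samples are flagged and logged; pelvic tilt never
approaches ±90° in walking data, so the branch exists for robustness, not
for routine use.

The variation series is the literal subtraction
`d(tᵢ) = θ(tᵢ) − θ(tᵢ₋₁)` by default (`wrap=False`).  When an angle
hovers near the ±π branch cut — the heading does exactly this after a
180° turn — the literal difference contains ±2π jumps, which inflate the
per-axis extremes and SD.  Those jumps are a real feature of analyzing
atan2 output and are kept by default; `wrap=True` folds each difference
into (−π, π] for users who want pure motion increments.  Differencing is
index-based over consecutive retained samples regardless of their time
gap; a gap exceeding twice the nominal 20 ms spacing is logged.

## Statistics and reporting

Per axis the pipeline reports maximum, minimum, arithmetic mean, sample
variance (divisor N−1) and SD, all unrounded in the returned objects.
Sample variance was fixed over the population estimator for determinism of
the contract; at N ≈ 10⁴ the two differ far below print precision.  The
text report rounds to three decimals with round-half-even and strips
trailing zeros, which is why a variance of 1.6·10⁻⁵ prints as `0` on the
same row whose SD prints as `0.004`.  The mean of each axis telescopes to
`(θ_last − θ_first)/(N−1)`, so a walk that ends in its starting
orientation reports means that round to 0 — a structural property the
acceptance script exercises.

The standard error of each mean (`sd/√N`) and a model-based sway-amplitude
estimate are exposed on the results object as diagnostics; the headline
table deliberately stays at the five descriptive statistics.

## Trimming

The first and last 10 s of a session are removed (start/stop button
transients).  Trimming is time-based on a closed interval: retained
samples satisfy `head ≤ t ≤ t_end − tail`, ties kept.  Whether the
protocol intends wall-clock or sample-count trimming is ambiguous; for the
regular 50-Hz grid the two coincide, and time-based trimming degrades
gracefully on irregular data.

## Synthetic gait generator

`GaitParams` encodes the emulated protocol: a 270-s walk (mid-range of the
4–5-minute out-and-back session) sampled every 20 ms, single-harmonic
pelvic sway `θ•(t) = amp•·sin(2πf t + phase•)` at a typical 1.8 Hz step
frequency with default amplitudes (0.05, 0.02, 0.04) rad, and a 180°
heading turn ramped linearly over 2 s at each programmed turn time
(default: one turn at mid-walk; a second turn can be added to close the
walk's orientation).  The heading ramp lives on θz — the rotation about
world-up under this convention; it cannot live on θy, whose extraction
range is hard-limited to ±π/2.  An `asym_bias` adds a constant offset to
θx during one half-cycle of the sway, a minimal left/right imbalance whose
zero-crossing discontinuities widen SD(dx) the way an impaired gait widens
the x/z statistics relative to a balanced one.

Sensors are synthesized exactly from the true orientation — gravity
`Rᵀ(0,0,9.81)` m/s², magnetometer `Rᵀ(0, B·cos I, −B·sin I)` with
B = 48 µT and inclination I = 60° (mid-latitude nominal values; fusion is
scale-invariant, so they only matter through the 30° gravity–field angle,
comfortably above the degeneracy threshold) — plus seeded white Gaussian
noise, 0.05 m/s² and 0.5 µT by default (representative consumer-MEMS
figures).  The accelerometer column duplicates gravity for schema
completeness; linear acceleration, foot-strike events, double-support
phases and gyroscope output are not modeled.  Identical parameters
(including the seed) produce bit-identical recordings.

The single harmonic is the smallest model with a closed form linking the
reported statistic to a gait parameter: for `θ = A sin(2πft)` sampled at
Δt, the difference SD is `2A sin(πfΔt)/√2 ≈ A·2πfΔt/√2` (the small-angle
form is 0.2% low at fΔt = 0.036), which `recover_params` inverts.  What
passing tests therefore show is that the pipeline measures *orientation
variability* correctly and traceably — not that real pathological gait is
sinusoidal.  Real recordings add harmonics, linear-acceleration leakage
into the gravity channel, magnetic disturbance indoors, and stride-to-stride
timing variability, none of which the generator emulates; conclusions about
patients require real data.

## Numerical choices

- Timestamps are stored as integer milliseconds (the platform's native
  unit) and held as float seconds; the simulator generates on the
  millisecond grid so files round-trip bit-exactly (shortest-repr floats
  on write, round-trip parsing on read).
- Orthonormality and determinant of every produced rotation matrix hold
  to 1e-9; fusion/extraction round trips hold to 1e-6 under synthesized
  sensors and 1e-9 matrix-to-angles.
- Angle wrapping uses the (−π, π] branch of atan2 throughout.
- Report rounding is decimal round-half-even at 3 places, applied only at
  formatting time.
- Recordings keep their original timestamps after trimming (no re-zeroing).
- A recording whose duration does not exceed head + tail trim windows is an
  error, as is a variation series built from fewer than two samples.

## Problem sizes

Tests run simulations of 30–270 s at 50 Hz (1.5k–13.5k samples) — the full
protocol length where a closed-form comparison is made (amplitude recovery,
closed-walk means), shorter walks where only structure is checked.  The
acceptance script runs the complete 270-s pipeline (13,501 samples, 12,500
differences after trimming).

## Known limitations

- Magnetic-ENU world frame: headings are relative to magnetic north.
- The gravity channel is trusted as gravity; during brisk accelerations a
  real device's gravity estimate lags, which no desk simulation captures.
- `recover_params` assumes straight-walk segments; heading turns and
  branch jumps inflate SD(dz) and bias the z-amplitude estimate upward.
- Scatter plots are pure per-sample scatter; no step segmentation or
  spectral analysis is provided.
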