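"""Synthetic waist-worn walking recordings with known ground truth.

No public deposit of the original participant recordings exists, so every
stage of the pipeline is exercised against a generator with fully known
parameters.  The kinematic model is deliberately minimal: each body angle
sways as a single sinusoid at the step frequency,

    θ•(t) = amp• · sin(2π f t + phase•)   (+ imbalance bias on θx),

the heading (θz, rotation about world-up) additionally ramps by 180° over a
couple of seconds at each programmed turn of the out-and-back protocol, and
the sensor streams are what an ideal gravity/magnetometer pair would read
in that orientation plus white Gaussian noise.  A single harmonic keeps the
first-difference statistics in closed form: for fΔt well below 1, the SD of
the per-sample angle differences is amp · 2πf · Δt / √2, which is what
:func:`recover_params` inverts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .fusion import RotationSeries
from .io import DEFAULT_DT, ImuRecording, ParticipantMeta
from .rotation import EulerSeries, euler_to_matrix, wrap_angle

#: standard gravity magnitude used for the synthetic gravity channel, m/s²
GRAVITY = 9.81


@dataclass
class GaitParams:
    """Parameters of one simulated walk.

    Defaults describe the recording protocol being emulated: a 4–5 minute
    out-and-back indoor walk (270 s), sampled every 20 ms, with a 180°
    heading turn halfway, pelvic sway at a typical 1.8 Hz step frequency,
    and consumer-MEMS noise levels on the synthesized sensors.

    ``amp`` holds the sway amplitudes in radians for (θx, θy, θz);
    ``asym_bias`` adds a constant offset to θx during one half-cycle of the
    sway, a crude left/right imbalance.  ``turn_times`` lists the start
    times of 180° heading turns (``None`` → one turn at duration/2; ``()``
    → straight walk).  The geomagnetic field is parameterized by total
    strength and inclination (dip) angle.
    """

    duration: float = 270.0
    dt: float = DEFAULT_DT
    step_freq: float = 1.8
    amp: Tuple[float, float, float] = (0.05, 0.02, 0.04)
    phase: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    turn_times: Optional[Tuple[float, ...]] = None
    turn_duration: float = 2.0
    asym_bias: float = 0.0
    noise_sd_grav: float = 0.05
    noise_sd_mag: float = 0.5
    field_strength: float = 48.0
    inclination_deg: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.duration > 2 * self.dt:
            raise ValueError("duration must exceed 2*dt")
        if self.step_freq < 0:
            raise ValueError("step_freq must be non-negative")
        self.amp = tuple(float(a) for a in self.amp)
        self.phase = tuple(float(p) for p in self.phase)
        if len(self.amp) != 3 or len(self.phase) != 3:
            raise ValueError("amp and phase must have 3 components")
        if any(a < 0 for a in self.amp):
            raise ValueError("sway amplitudes must be non-negative")
        if self.turn_times is None:
            self.turn_times = (self.duration / 2.0,)
        else:
            self.turn_times = tuple(float(t) for t in self.turn_times)
        if any(not 0 < t0 < self.duration for t0 in self.turn_times):
            raise ValueError("turn times must lie strictly inside the walk")
        if not self.turn_duration > 0:
            raise ValueError("turn_duration must be positive")
        if self.noise_sd_grav < 0 or self.noise_sd_mag < 0:
            raise ValueError("noise SDs must be non-negative")
        if not self.field_strength > 0:
            raise ValueError("field_strength must be positive")


@dataclass
class GroundTruth:
    """True orientation trajectory of a simulated walk."""

    euler: EulerSeries
    rotations: RotationSeries


def _heading(t: np.ndarray, p: GaitParams) -> np.ndarray:
    """Cumulative heading from the programmed turns: +π ramped over each turn."""
    h = np.zeros_like(t)
    for t0 in p.turn_times:
        h += math.pi * np.clip((t - t0) / p.turn_duration, 0.0, 1.0)
    return h


def simulate_orientation(p: GaitParams) -> GroundTruth:
    """Generate the ground-truth angle and rotation-matrix trajectories.

    Deterministic (no noise enters here).  The stored θz is wrapped into
    (−π, π], the branch the matrix extraction can actually return, and the
    matrices are composed from the stored angles, so the two ground-truth
    views are exactly consistent.
    """
    n = int(math.floor(p.duration / p.dt)) + 1
    # keep timestamps on the integer-millisecond grid the file format stores
    t = np.rint(np.arange(n) * (p.dt * 1000.0)) / 1000.0
    w = 2.0 * math.pi * p.step_freq
    sway_x = np.sin(w * t + p.phase[0])
    tx = p.amp[0] * sway_x
    if p.asym_bias:
        tx = tx + p.asym_bias * (sway_x > 0)
    ty = p.amp[1] * np.sin(w * t + p.phase[1])
    tz = p.amp[2] * np.sin(w * t + p.phase[2]) + _heading(t, p)
    tz = wrap_angle(tz)
    R = euler_to_matrix(tx, ty, tz)
    euler = EulerSeries(t=t, theta_x=tx, theta_y=ty, theta_z=tz)
    return GroundTruth(euler=euler, rotations=RotationSeries(t=t.copy(), R=R))


def geomagnetic_field(p: GaitParams) -> np.ndarray:
    """World-frame (East, North, Up) geomagnetic vector, µT."""
    inc = math.radians(p.inclination_deg)
    return np.array([0.0,
                     p.field_strength * math.cos(inc),
                     -p.field_strength * math.sin(inc)])


def synthesize_sensors(gt: GroundTruth, p: GaitParams,
                       meta: Optional[ParticipantMeta] = None) -> ImuRecording:
    """Synthesize the device-frame sensor streams for a true trajectory.

    Per sample, gravity = Rᵀ·(0, 0, 9.81) and the magnetometer reads
    Rᵀ·(0, B·cos I, −B·sin I) (B field strength, I inclination), plus
    seeded Gaussian noise.  The accelerometer column duplicates gravity (no
    linear acceleration is modeled) and the gyroscope is omitted.
    """
    R = gt.rotations.R
    u = np.array([0.0, 0.0, GRAVITY])
    f = geomagnetic_field(p)
    # v_device = Rᵀ v_world
    grav = np.einsum("nji,j->ni", R, u)
    mag = np.einsum("nji,j->ni", R, f)
    rng = np.random.default_rng(p.seed)
    if p.noise_sd_grav > 0:
        grav = grav + rng.normal(0.0, p.noise_sd_grav, grav.shape)
    if p.noise_sd_mag > 0:
        mag = mag + rng.normal(0.0, p.noise_sd_mag, mag.shape)
    return ImuRecording(
        t=gt.rotations.t.copy(),
        accel=grav.copy(),
        gravity=grav,
        magnetic=mag,
        meta=meta if meta is not None else ParticipantMeta(),
        nominal_dt=p.dt,
    )


def simulate_recording(p: GaitParams,
                       meta: Optional[ParticipantMeta] = None
                       ) -> Tuple[GroundTruth, ImuRecording]:
    """Convenience: ground truth plus its synthesized recording."""
    gt = simulate_orientation(p)
    return gt, synthesize_sensors(gt, p, meta=meta)


@dataclass
class AmplitudeRecovery:
    """Sway amplitudes estimated from a variation series vs the true values."""

    estimated: np.ndarray
    true: np.ndarray

    @property
    def relative_error(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.true > 0,
                            self.estimated / self.true - 1.0, 0.0)


def recover_params(vs, p_nominal: GaitParams) -> AmplitudeRecovery:
    """Invert the sinusoid's difference-SD relation to estimate amplitudes.

    For θ(t) = A sin(2πft) sampled at Δt, SD of the first differences is
    A·2πf·Δt/√2 to first order in fΔt, so Â = SD(d)·√2 / (2πf·Δt).  Only
    meaningful for straight-walk segments (heading turns and branch jumps
    inflate the SD).
    """
    if p_nominal.step_freq <= 0 or p_nominal.dt <= 0:
        raise ValueError("step_freq and dt must be positive to invert")
    scale = math.sqrt(2.0) / (2.0 * math.pi * p_nominal.step_freq * p_nominal.dt)
    sds = np.array([np.std(vs.axis(ax), ddof=1) for ax in ("x", "y", "z")])
    return AmplitudeRecovery(estimated=sds * scale,
                             true=np.asarray(p_nominal.amp, dtype=float))


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write the true angle trajectory as CSV (t_ms, theta_x, theta_y, theta_z)."""
    pd.DataFrame({
        "t_ms": np.rint(gt.euler.t * 1000.0).astype(np.int64),
        "theta_x": gt.euler.theta_x,
        "theta_y": gt.euler.theta_y,
        "theta_z": gt.euler.theta_z,
    }).to_csv(Path(path), index=False,
              float_format=lambda v: repr(float(v)))
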