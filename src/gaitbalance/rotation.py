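"""Euler-angle extraction, variation series, and summary statistics.

The analysis reduces each 3x3 device-to-world rotation matrix to three
Tait–Bryan angles (θx, θy, θz) under the ZYX convention,
``R = Rz(θz) @ Ry(θy) @ Rx(θx)``::

    θx = atan2(R32, R33)
    θy = atan2(-R31, sqrt(R32² + R33²))
    θz = atan2(R21, R11)

Against the body of a walker wearing the device at the waist, θx tracks
right(−)/left(+) motion, θy up(−)/down(+) motion and θz forward(+)/
backward(−) motion.  Because each wearer straps the device at a slightly
different resting slope, the analysis object is not the angles themselves
but their per-sample first differences, d(t_i) = θ(t_i) − θ(t_{i−1}) — the
*variation series* — whose spread per axis quantifies walking balance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AXES = ("x", "y", "z")

#: |R31| above this is treated as gimbal lock (θy within ~4e-5 rad of ±π/2)
GIMBAL_TOL = 1e-9


@dataclass
class EulerSeries:
    """Per-sample rotation angles, radians.

    θx, θz lie in (−π, π], θy in [−π/2, π/2] (atan2 ranges of the ZYX
    extraction).  ``gimbal_locked`` optionally flags samples extracted at
    the θy = ±π/2 degeneracy.
    """

    t: np.ndarray
    theta_x: np.ndarray
    theta_y: np.ndarray
    theta_z: np.ndarray
    gimbal_locked: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("theta_x", "theta_y", "theta_z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} must match t in length")
            setattr(self, name, arr)
        if self.gimbal_locked is not None:
            self.gimbal_locked = np.asarray(self.gimbal_locked, dtype=bool)

    def __len__(self) -> int:
        return int(self.t.size)

    def angles(self) -> np.ndarray:
        """Angles stacked as an (n, 3) array in x, y, z order."""
        return np.stack([self.theta_x, self.theta_y, self.theta_z], axis=1)


@dataclass
class VariationSeries:
    """First differences of an :class:`EulerSeries`, radians.

    ``t`` carries the timestamp of the *current* sample of each difference,
    so all four arrays have length N−1.
    """

    t: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("dx", "dy", "dz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} must match t in length")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return int(self.t.size)

    def axis(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {name!r}")
        return getattr(self, "d" + name)


@dataclass
class AxisSummary:
    """Five-number summary of one variation axis (all in radians / radians²)."""

    maximum: float
    minimum: float
    mean: float
    variance: float
    sd: float

    def __post_init__(self) -> None:
        # 1-ulp-scale slack: the mean of identical values can overshoot the
        # max by float-summation rounding
        tol = 1e-12 * max(1.0, abs(self.maximum), abs(self.minimum))
        if not (self.minimum - tol <= self.mean <= self.maximum + tol):
            raise ValueError("mean must lie between minimum and maximum")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


def wrap_angle(x):
    """Map angles into (−π, π], matching the atan2 branch."""
    x = np.asarray(x, dtype=float)
    w = np.mod(x + np.pi, 2.0 * np.pi) - np.pi
    # mod puts the boundary at −π; atan2 puts it at +π
    w = np.where(w == -np.pi, np.pi, w)
    return w if w.ndim else float(w)


def _euler_from_stack(R: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ZYX extraction over an (n, 3, 3) stack."""
    r31 = R[:, 2, 0]
    locked = np.abs(r31) >= 1.0 - GIMBAL_TOL
    ty = np.arctan2(-r31, np.hypot(R[:, 2, 1], R[:, 2, 2]))
    tx = np.arctan2(R[:, 2, 1], R[:, 2, 2])
    tz = np.arctan2(R[:, 1, 0], R[:, 0, 0])
    if np.any(locked):
        # θy = ±π/2: only θx ∓ θz is determined; put it all in θx, zero θz.
        sign = np.where(r31[locked] < 0, 1.0, -1.0)  # sign of θy
        tx = tx.copy(); ty = ty.copy(); tz = tz.copy()
        tx[locked] = np.arctan2(sign * R[locked, 0, 1], R[locked, 1, 1])
        ty[locked] = sign * (np.pi / 2.0)
        tz[locked] = 0.0
    return tx, ty, tz, locked


def euler_from_matrix(R) -> Tuple[float, float, float]:
    """Extract (θx, θy, θz) from a proper-orthogonal 3x3 matrix.

    At gimbal lock (|R31| = 1, i.e. θy = ±π/2) only the combination
    θx ∓ θz is defined; the whole free angle is assigned to θx and θz is
    set to 0, which still reconstructs ``R`` exactly.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("R must be a 3x3 matrix")
    tx, ty, tz, locked = _euler_from_stack(R[None, :, :])
    if locked[0]:
        logger.warning("gimbal-lock input to euler_from_matrix (|theta_y| = pi/2)")
    return float(tx[0]), float(ty[0]), float(tz[0])


def euler_to_matrix(theta_x, theta_y, theta_z) -> np.ndarray:
    """Compose ``Rz(θz) @ Ry(θy) @ Rx(θx)``.

    Accepts scalars (returns (3, 3)) or equal-length arrays (returns
    (n, 3, 3)); the inverse of :func:`euler_from_matrix` away from gimbal
    lock.
    """
    a = np.asarray(theta_x, dtype=float)
    b = np.asarray(theta_y, dtype=float)
    c = np.asarray(theta_z, dtype=float)
    scalar = a.ndim == 0
    a, b, c = np.atleast_1d(a, b, c)
    sa, ca = np.sin(a), np.cos(a)
    sb, cb = np.sin(b), np.cos(b)
    sc, cc = np.sin(c), np.cos(c)
    R = np.empty((a.size, 3, 3))
    R[:, 0, 0] = cb * cc
    R[:, 0, 1] = sa * sb * cc - ca * sc
    R[:, 0, 2] = ca * sb * cc + sa * sc
    R[:, 1, 0] = cb * sc
    R[:, 1, 1] = sa * sb * sc + ca * cc
    R[:, 1, 2] = ca * sb * sc - sa * cc
    R[:, 2, 0] = -sb
    R[:, 2, 1] = sa * cb
    R[:, 2, 2] = ca * cb
    return R[0] if scalar else R


def extract_series(rs) -> EulerSeries:
    """Apply :func:`euler_from_matrix` to every matrix of a rotation series."""
    if len(rs) == 0:
        raise ValueError("rotation series is empty")
    tx, ty, tz, locked = _euler_from_stack(rs.R)
    n_lock = int(np.sum(locked))
    if n_lock:
        logger.warning("%d gimbal-locked sample(s) in extraction", n_lock)
    return EulerSeries(t=rs.t.copy(), theta_x=tx, theta_y=ty, theta_z=tz,
                       gimbal_locked=locked)


def diff_series(es: EulerSeries, wrap: bool = False) -> VariationSeries:
    """Per-sample first differences d(t_i) = θ(t_i) − θ(t_{i−1}).

    With ``wrap=True`` each difference is mapped into (−π, π], removing the
    ±2π jumps that the atan2 branch cut produces when an angle crosses ±π.
    The default is the literal subtraction.
    """
    if len(es) < 2:
        raise ValueError("need at least 2 samples to difference")
    dx = np.diff(es.theta_x)
    dy = np.diff(es.theta_y)
    dz = np.diff(es.theta_z)
    if wrap:
        dx, dy, dz = wrap_angle(dx), wrap_angle(dy), wrap_angle(dz)
    return VariationSeries(t=es.t[1:].copy(), dx=dx, dy=dy, dz=dz)


def summarize(vs: VariationSeries) -> Dict[str, AxisSummary]:
    """Per-axis max, min, mean, sample variance (N−1) and SD, unrounded.

    A single-difference series has undefined sample variance; it is
    reported as 0.
    """
    if len(vs) == 0:
        raise ValueError("variation series is empty")
    out: Dict[str, AxisSummary] = {}
    for ax in AXES:
        d = vs.axis(ax)
        var = float(np.var(d, ddof=1)) if d.size > 1 else 0.0
        out[ax] = AxisSummary(
            maximum=float(np.max(d)),
            minimum=float(np.min(d)),
            mean=float(np.mean(d)),
            variance=var,
            sd=math.sqrt(var),
        )
    return out


def _fmt3(x: float) -> str:
    """Round to 3 decimals (half-even) and strip trailing zeros: 0.13, 0.004, 0."""
    d = Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN)
    if d == 0:
        return "0"
    s = format(d.normalize(), "f")
    return s


SummaryMapping = Mapping[str, Mapping[str, AxisSummary]]


def report_frame(summaries: SummaryMapping) -> pd.DataFrame:
    """Tidy unrounded table: participant, axis, max, min, mean, variance, sd."""
    rows = []
    for participant, per_axis in summaries.items():
        for ax in AXES:
            s = per_axis[ax]
            rows.append({
                "participant": participant, "axis": ax,
                "max": s.maximum, "min": s.minimum, "mean": s.mean,
                "variance": s.variance, "sd": s.sd,
            })
    return pd.DataFrame(rows)


def format_report(summaries: SummaryMapping) -> str:
    """Plain-text statistics table, one x/y/z block per participant.

    Values are rounded to three decimals with banker's rounding; trailing
    zeros are stripped (a variance of 1.6e-5 prints as ``0`` even while the
    matching SD prints as ``0.004``).
    """
    if not summaries:
        raise ValueError("no summaries to report")
    header = ["Maximum", "Minimum", "Mean", "Variance", "SD"]
    lines = ["{:<30}".format("Participant, rotation vector")
             + "".join(f"{h:>10}" for h in header)]
    for participant, per_axis in summaries.items():
        lines.append(str(participant))
        for ax in AXES:
            s = per_axis[ax]
            vals = [s.maximum, s.minimum, s.mean, s.variance, s.sd]
            lines.append("  {:<28}".format(f"{ax}-axis")
                         + "".join(f"{_fmt3(v):>10}" for v in vals))
    return "\n".join(lines) + "\n"


def pairwise_scatter(
    vs: Union[VariationSeries, Mapping[str, VariationSeries]],
    axes: Tuple[str, str],
    path,
    participant: Optional[str] = None,
) -> None:
    """Scatter one variation axis against another, one panel per participant.

    Draws zero lines and keeps an equal aspect so left/right and
    forward/backward asymmetries are visually comparable.
    """
    import matplotlib.pyplot as plt

    a, b = axes
    if a == b or a not in AXES or b not in AXES:
        raise ValueError(f"axes must be two distinct members of {AXES}")
    if isinstance(vs, VariationSeries):
        mapping: Mapping[str, VariationSeries] = {participant or "": vs}
    else:
        mapping = vs
    n = len(mapping)
    fig, axs = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for axplot, (name, series) in zip(axs[0], mapping.items()):
        axplot.scatter(series.axis(a), series.axis(b), s=4, alpha=0.4,
                       linewidths=0)
        axplot.axhline(0.0, color="0.6", lw=0.8)
        axplot.axvline(0.0, color="0.6", lw=0.8)
        axplot.set_aspect("equal", adjustable="datalim")
        axplot.set_xlabel(f"d{a} (rad)")
        axplot.set_ylabel(f"d{b} (rad)")
        if name:
            axplot.set_title(name)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
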