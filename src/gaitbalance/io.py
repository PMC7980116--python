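"""Reading, writing and trimming waist-worn IMU walking recordings.

The on-disk format is the export schema of the recording app: a purely
numeric, comma-separated sensor table with one header row and one row per
sample, plus an optional JSON sidecar (``<basename>.meta.json``) holding the
participant questionnaire.  Timestamps are stored as integer milliseconds
since the start of the recording and held in memory as float seconds.

Columns, in order::

    t_ms, acc_x, acc_y, acc_z, gyro_x, gyro_y, gyro_z,
    grav_x, grav_y, grav_z, mag_x, mag_y, mag_z,
    r11, r12, r13, r21, r22, r23, r31, r32, r33

The gyroscope and rotation-matrix columns are optional; absent channels are
simply omitted from the header.  Accelerometer and gravity are in m/s²,
the magnetometer in µT, the gyroscope in rad/s.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "t_ms",
    "acc_x", "acc_y", "acc_z",
    "grav_x", "grav_y", "grav_z",
    "mag_x", "mag_y", "mag_z",
]
GYRO_COLUMNS = ["gyro_x", "gyro_y", "gyro_z"]
ROTMAT_COLUMNS = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]

#: nominal sample spacing of the recording app, seconds (one sample / 20 ms)
DEFAULT_DT = 0.020


@dataclass
class ParticipantMeta:
    """Participant questionnaire attached to a recording.

    Every field is optional (``None`` = not recorded).  ``pain_status`` is a
    free set such as ``"back"``, ``"leg"``, ``"head"`` or ``"none"``.
    ``valid_test`` mirrors the operator checkbox marking whether the walk was
    interrupted.
    """

    participant_id: Optional[str] = None
    pain_status: Optional[str] = None
    medication_3day: Optional[bool] = None
    walking_problem: Optional[bool] = None
    concussion: Optional[bool] = None
    gender: Optional[str] = None
    race_ethnicity: Optional[str] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    valid_test: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.height_cm is not None and not self.height_cm > 0:
            raise ValueError("height_cm must be positive when present")
        if self.weight_kg is not None and not self.weight_kg > 0:
            raise ValueError("weight_kg must be positive when present")


@dataclass
class ImuSample:
    """A single multi-channel sensor sample (view into an :class:`ImuRecording`)."""

    t: float
    accel: np.ndarray
    gravity: np.ndarray
    magnetic: np.ndarray
    gyro: Optional[np.ndarray] = None
    rotmat: Optional[np.ndarray] = None


@dataclass
class ImuRecording:
    """A timestamped multi-channel sensor series with participant metadata.

    Arrays are stored channel-major: ``t`` has shape ``(n,)`` (seconds,
    strictly increasing, starting at or after 0), the vector channels have
    shape ``(n, 3)`` and the optional stored rotation matrices ``(n, 3, 3)``.
    """

    t: np.ndarray
    accel: np.ndarray
    gravity: np.ndarray
    magnetic: np.ndarray
    gyro: Optional[np.ndarray] = None
    rotmat: Optional[np.ndarray] = None
    meta: ParticipantMeta = field(default_factory=ParticipantMeta)
    nominal_dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size == 0:
            raise ValueError("t must be a non-empty 1-D array")
        if self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.nominal_dt > 0:
            raise ValueError("nominal_dt must be positive")
        n = self.t.size
        for name in ("accel", "gravity", "magnetic"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
            setattr(self, name, arr)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
            if self.gyro.shape != (n, 3):
                raise ValueError(f"gyro must have shape ({n}, 3)")
        if self.rotmat is not None:
            self.rotmat = np.asarray(self.rotmat, dtype=float)
            if self.rotmat.shape != (n, 3, 3):
                raise ValueError(f"rotmat must have shape ({n}, 3, 3)")
        if n > 1:
            gaps = int(np.sum(np.diff(self.t) > 2 * self.nominal_dt))
            if gaps:
                logger.warning(
                    "recording has %d inter-sample gap(s) exceeding 2x the "
                    "nominal %.0f ms spacing", gaps, self.nominal_dt * 1e3,
                )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Elapsed time between first and last sample, seconds."""
        return float(self.t[-1] - self.t[0])

    def samples(self) -> Iterator[ImuSample]:
        """Iterate over per-sample views."""
        for i in range(len(self)):
            yield ImuSample(
                t=float(self.t[i]),
                accel=self.accel[i],
                gravity=self.gravity[i],
                magnetic=self.magnetic[i],
                gyro=None if self.gyro is None else self.gyro[i],
                rotmat=None if self.rotmat is None else self.rotmat[i],
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def read_recording(
    path,
    delimiter: str = ",",
    nominal_dt: float = DEFAULT_DT,
) -> ImuRecording:
    """Read a sensor CSV (and its metadata sidecar, if present).

    Raises :class:`ValueError` for an empty file, missing required columns,
    a malformed cell (named by line number), or non-monotonic timestamps.
    """
    path = Path(path)
    try:
        # round_trip parsing: stored shortest-repr floats come back bit-exact
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    known = set(REQUIRED_COLUMNS) | set(GYRO_COLUMNS) | set(ROTMAT_COLUMNS)
    for c in [c for c in df.columns if c in known]:
        num = pd.to_numeric(df[c], errors="coerce")
        bad = num.isna()
        if bad.any():
            # header is line 1, first data row line 2
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: malformed value in column '{c}' at line {line}"
            )
        df[c] = num.astype(float)

    t = df["t_ms"].to_numpy(dtype=float) / 1000.0
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: non-monotonic timestamps")

    def _vec(cols):
        return df[cols].to_numpy(dtype=float)

    gyro = _vec(GYRO_COLUMNS) if all(c in df.columns for c in GYRO_COLUMNS) else None
    rotmat = None
    if all(c in df.columns for c in ROTMAT_COLUMNS):
        rotmat = _vec(ROTMAT_COLUMNS).reshape(-1, 3, 3)

    meta = ParticipantMeta()
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = ParticipantMeta(**json.load(fh))

    return ImuRecording(
        t=t,
        accel=_vec(["acc_x", "acc_y", "acc_z"]),
        gravity=_vec(["grav_x", "grav_y", "grav_z"]),
        magnetic=_vec(["mag_x", "mag_y", "mag_z"]),
        gyro=gyro,
        rotmat=rotmat,
        meta=meta,
        nominal_dt=nominal_dt,
    )


def write_recording(rec: ImuRecording, path) -> None:
    """Write ``rec`` as a sensor CSV plus a ``.meta.json`` sidecar.

    Floats are written with shortest round-trip precision, so
    ``read_recording(write_recording(rec))`` reproduces every numeric field
    bit-for-bit as long as timestamps lie on the millisecond grid.
    """
    path = Path(path)
    data: dict[str, np.ndarray] = {
        "t_ms": np.rint(rec.t * 1000.0).astype(np.int64)
    }
    for prefix, arr in (("acc", rec.accel), ("gyro", rec.gyro),
                        ("grav", rec.gravity), ("mag", rec.magnetic)):
        if arr is None:
            continue
        for j, axis in enumerate("xyz"):
            data[f"{prefix}_{axis}"] = arr[:, j]
    if rec.rotmat is not None:
        flat = rec.rotmat.reshape(-1, 9)
        for k, name in enumerate(ROTMAT_COLUMNS):
            data[name] = flat[:, k]
    # repr = shortest round-trip float text; default formatting loses a ulp
    pd.DataFrame(data).to_csv(path, index=False,
                              float_format=lambda v: repr(float(v)))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(dataclasses.asdict(rec.meta), fh, indent=1)


def trim_recording(
    rec: ImuRecording, head_s: float = 10.0, tail_s: float = 10.0
) -> ImuRecording:
    """Drop the opening ``head_s`` and closing ``tail_s`` seconds.

    Retains exactly the samples with ``head_s <= t <= t_end - tail_s``
    (closed interval on both sides; a sample at exactly the boundary is
    kept).  This removes the operator's start/stop button-press transients.
    """
    if head_s < 0 or tail_s < 0:
        raise ValueError("trim windows must be non-negative")
    t = rec.t
    t_end = float(t[-1])
    if rec.duration <= head_s + tail_s:
        raise ValueError(
            f"recording too short to trim: duration {rec.duration:.3f} s "
            f"<= head {head_s:g} s + tail {tail_s:g} s"
        )
    eps = 1e-9
    mask = (t >= head_s - eps) & (t <= t_end - tail_s + eps)
    if int(mask.sum()) < 2:
        raise ValueError("fewer than 2 samples remain after trimming")
    return ImuRecording(
        t=t[mask].copy(),
        accel=rec.accel[mask].copy(),
        gravity=rec.gravity[mask].copy(),
        magnetic=rec.magnetic[mask].copy(),
        gyro=None if rec.gyro is None else rec.gyro[mask].copy(),
        rotmat=None if rec.rotmat is None else rec.rotmat[mask].copy(),
        meta=rec.meta,
        nominal_dt=rec.nominal_dt,
    )
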