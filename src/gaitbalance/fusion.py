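"""Two-vector (gravity + geomagnetic) attitude determination.

A waist-worn phone reports a gravity vector (a "down" reference) and a
geomagnetic vector (a "north" reference) in its own device frame.  From one
simultaneous pair, the device-to-world rotation matrix follows from a
normalized triad of cross products — the same construction the Android
``SensorManager.getRotationMatrix`` call performs:

    A = g / |g|                 (world Up, in device coordinates)
    H = (m x g) / |m x g|       (world East)
    M = A x H                   (world North)

The rows of ``R = [H; M; A]`` are the East, North and Up unit directions
expressed in device coordinates, so ``v_world = R @ v_device`` with the
world frame (East, North, Up), North meaning magnetic north.  The
construction fails when gravity and the field are (near-)parallel — free
fall, or standing on a magnetic pole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: default degeneracy threshold: minimum |sin(angle)| between the two
#: reference vectors, matching the platform's documented failure condition
MIN_REL_CROSS = 0.1


class DegenerateGeometryError(ValueError):
    """Gravity and magnetic field too close to parallel to fix a frame."""


def is_rotation(R, tol: float = 1e-9) -> bool:
    """True if ``R`` is orthonormal with det +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    return bool(err <= tol and abs(np.linalg.det(R) - 1.0) <= tol)


@dataclass
class RotationSeries:
    """Per-sample device-to-world rotation matrices.

    ``t`` has shape ``(n,)`` (seconds, strictly increasing), ``R`` shape
    ``(n, 3, 3)`` row-major.
    """

    t: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.ndim != 1 or self.t.size == 0:
            raise ValueError("t must be a non-empty 1-D array")
        if self.R.shape != (self.t.size, 3, 3):
            raise ValueError("R must have shape (len(t), 3, 3)")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    def max_orthonormality_error(self) -> float:
        """Largest elementwise deviation of R^T R from I over the series."""
        rtr = np.einsum("nji,njk->nik", self.R, self.R)
        return float(np.max(np.abs(rtr - np.eye(3))))


def fuse(gravity, magnetic, *, min_rel_cross: float = MIN_REL_CROSS) -> np.ndarray:
    """Device-to-world rotation matrix from one gravity/magnetometer pair.

    Parameters
    ----------
    gravity : 3-vector, m/s² (any positive scale; only direction matters)
    magnetic : 3-vector, µT
    min_rel_cross : degeneracy threshold on |m x g| / (|m| |g|), i.e. the
        sine of the angle between the two references.

    Returns
    -------
    (3, 3) ndarray, proper orthogonal: rows are world East, North, Up in
    device coordinates.
    """
    g = np.asarray(gravity, dtype=float)
    m = np.asarray(magnetic, dtype=float)
    ng = float(np.linalg.norm(g))
    nm = float(np.linalg.norm(m))
    if ng == 0.0 or nm == 0.0:
        raise ValueError("gravity and magnetic vectors must be non-zero")
    h = np.cross(m, g)
    nh = float(np.linalg.norm(h))
    if nh < min_rel_cross * ng * nm:
        raise DegenerateGeometryError(
            "gravity and magnetic field are near-parallel "
            f"(relative cross-product norm {nh / (ng * nm):.3g} "
            f"< {min_rel_cross:g})"
        )
    H = h / nh
    A = g / ng
    M = np.cross(A, H)
    return np.stack([H, M, A])


def fuse_series(rec, *, min_rel_cross: float = MIN_REL_CROSS) -> RotationSeries:
    """Fuse every sample of a recording into a rotation series.

    Samples with zero-norm references or degenerate geometry are dropped
    (never zero-filled); the dropped count is logged.  Raises
    :class:`DegenerateGeometryError` if nothing survives.
    """
    g = rec.gravity
    m = rec.magnetic
    ng = np.linalg.norm(g, axis=1)
    nm = np.linalg.norm(m, axis=1)
    h = np.cross(m, g)
    nh = np.linalg.norm(h, axis=1)
    ok = (ng > 0) & (nm > 0) & (nh >= min_rel_cross * ng * nm)
    n_drop = int(np.sum(~ok))
    if not np.any(ok):
        raise DegenerateGeometryError(
            "all samples have degenerate gravity/magnetic geometry"
        )
    if n_drop:
        logger.warning(
            "dropped %d of %d sample(s) with degenerate gravity/magnetic "
            "geometry during fusion", n_drop, len(rec),
        )
    H = h[ok] / nh[ok, None]
    A = g[ok] / ng[ok, None]
    M = np.cross(A, H)
    R = np.stack([H, M, A], axis=1)  # rows of each matrix
    return RotationSeries(t=rec.t[ok].copy(), R=R)


def rotation_series(rec, *, use_stored: bool = True,
                    min_rel_cross: float = MIN_REL_CROSS) -> RotationSeries:
    """Rotation series for a recording: stored matrices when present, else fused.

    The recording app stores the platform-computed 3x3 matrix alongside the
    raw sensors; by default those are trusted when available and the
    gravity/magnetometer fusion is recomputed otherwise.
    """
    if use_stored and rec.rotmat is not None:
        return RotationSeries(t=rec.t.copy(), R=rec.rotmat.copy())
    return fuse_series(rec, min_rel_cross=min_rel_cross)
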