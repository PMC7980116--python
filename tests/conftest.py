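import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from gaitbalance import GaitParams, ImuRecording, ParticipantMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_recording(rng):
    """Factory for small valid recordings on the millisecond grid."""

    def _make(n=50, dt_ms=20, with_gyro=True, with_rotmat=False, meta=None):
        t = np.arange(n) * dt_ms / 1000.0
        gravity = np.array([0.0, 0.0, 9.81]) + rng.normal(0, 0.3, (n, 3))
        magnetic = np.array([0.0, 30.0, -40.0]) + rng.normal(0, 1.0, (n, 3))
        return ImuRecording(
            t=t,
            accel=gravity + rng.normal(0, 0.1, (n, 3)),
            gravity=gravity,
            magnetic=magnetic,
            gyro=rng.normal(0, 0.5, (n, 3)) if with_gyro else None,
            rotmat=np.tile(np.eye(3), (n, 1, 1)) if with_rotmat else None,
            meta=meta or ParticipantMeta(),
        )

    return _make


@pytest.fixture
def quiet_walk():
    """Noise-free straight-walk parameters for deterministic oracles."""
    return GaitParams(duration=60.0, noise_sd_grav=0.0, noise_sd_mag=0.0,
                      turn_times=(), seed=7)
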