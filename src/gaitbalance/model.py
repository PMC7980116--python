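"""Model/Results interface over the walking-balance pipeline.

:class:`WalkingBalance` is constructed from an :class:`~gaitbalance.io
.ImuRecording` (or its CSV) together with the analysis configuration;
:meth:`WalkingBalance.fit` runs trim → rotation matrices → Euler extraction
→ first differencing → per-axis summaries and returns a
:class:`WalkingBalanceResults` carrying every intermediate series, the
summary statistics, and plotting/reporting helpers.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np

from . import io as gio
from .fusion import RotationSeries, rotation_series
from .rotation import (
    AXES,
    AxisSummary,
    EulerSeries,
    VariationSeries,
    diff_series,
    extract_series,
    format_report,
    pairwise_scatter,
    report_frame,
    summarize,
)


class WalkingBalance:
    """Walking-balance measurement model for one waist-worn IMU recording.

    Parameters
    ----------
    recording : ImuRecording
        The sensor series to analyze.
    trim_head, trim_tail : float, seconds
        Head/tail windows removed before analysis (default 10 s each, the
        start/stop button-press transients).  Set both to 0 to disable.
    wrap : bool
        Map angle differences into (−π, π] instead of using the literal
        subtraction (default False).
    use_stored_rotation : bool
        Trust the 3x3 matrices stored in the recording when present;
        otherwise refuse them and recompute the gravity/magnetometer
        fusion (default True).
    participant : str, optional
        Label used in reports; falls back to the metadata participant id.
    """

    def __init__(
        self,
        recording: gio.ImuRecording,
        *,
        trim_head: float = 10.0,
        trim_tail: float = 10.0,
        wrap: bool = False,
        use_stored_rotation: bool = True,
        participant: Optional[str] = None,
    ) -> None:
        if len(recording) < 2:
            raise ValueError("need at least 2 samples to analyze")
        self.recording = recording
        self.trim_head = float(trim_head)
        self.trim_tail = float(trim_tail)
        self.wrap = bool(wrap)
        self.use_stored_rotation = bool(use_stored_rotation)
        self.participant = (participant or recording.meta.participant_id
                            or "participant")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "WalkingBalance":
        """Build the model straight from a sensor CSV (+ metadata sidecar)."""
        rec = gio.read_recording(path)
        return cls(rec, **kwargs)

    def fit(self) -> "WalkingBalanceResults":
        """Run the full pipeline and return the results object."""
        rec = self.recording
        if self.trim_head > 0 or self.trim_tail > 0:
            rec = gio.trim_recording(rec, self.trim_head, self.trim_tail)
        rotations = rotation_series(rec, use_stored=self.use_stored_rotation)
        euler = extract_series(rotations)
        variation = diff_series(euler, wrap=self.wrap)
        summaries = summarize(variation)
        return WalkingBalanceResults(
            model=self,
            trimmed=rec,
            rotations=rotations,
            euler=euler,
            variation=variation,
            summaries=summaries,
        )


class WalkingBalanceResults:
    """Fitted walking-balance statistics for one recording.

    Attributes
    ----------
    trimmed : ImuRecording
        The recording actually analyzed (after head/tail trimming).
    rotations, euler, variation :
        The intermediate series of the pipeline.
    summaries : dict axis -> AxisSummary
        Unrounded per-axis max/min/mean/variance/SD of the variation series.
    """

    def __init__(self, model, trimmed, rotations: RotationSeries,
                 euler: EulerSeries, variation: VariationSeries,
                 summaries: Dict[str, AxisSummary]) -> None:
        self.model = model
        self.trimmed = trimmed
        self.rotations = rotations
        self.euler = euler
        self.variation = variation
        self.summaries = summaries

    @property
    def participant(self) -> str:
        return self.model.participant

    @property
    def nobs(self) -> int:
        """Number of first differences entering the statistics."""
        return len(self.variation)

    @property
    def n_dropped(self) -> int:
        """Samples lost to degenerate gravity/magnetic geometry."""
        return len(self.trimmed) - len(self.rotations)

    @property
    def n_gimbal_locked(self) -> int:
        """Samples whose Euler extraction hit the θy = ±π/2 degeneracy."""
        if self.euler.gimbal_locked is None:
            return 0
        return int(np.sum(self.euler.gimbal_locked))

    def mean_se(self) -> Dict[str, float]:
        """Standard error of each per-axis mean, sd/√N."""
        n = self.nobs
        return {ax: self.summaries[ax].sd / math.sqrt(n) for ax in AXES}

    def sway_amplitude(self, step_freq: float) -> Dict[str, float]:
        """Sinusoidal sway amplitude implied by each axis SD, radians.

        Inverts SD(d) = A·2πf·Δt/√2 using the recording's nominal sample
        spacing; see :func:`gaitbalance.simulate.recover_params`.
        """
        if step_freq <= 0:
            raise ValueError("step_freq must be positive")
        dt = self.trimmed.nominal_dt
        scale = math.sqrt(2.0) / (2.0 * math.pi * step_freq * dt)
        return {ax: self.summaries[ax].sd * scale for ax in AXES}

    def to_frame(self):
        """Unrounded tidy summary table (one row per axis)."""
        return report_frame({self.participant: self.summaries})

    def summary(self) -> str:
        """Plain-text statistics table (3-decimal report rounding)."""
        return format_report({self.participant: self.summaries})

    def plot_pairwise(self, axes: Tuple[str, str], path) -> None:
        """Scatter one variation axis against another and save to ``path``."""
        pairwise_scatter(self.variation, axes, path,
                         participant=self.participant)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<WalkingBalanceResults {self.participant!r}: "
                f"nobs={self.nobs}, dropped={self.n_dropped}>")
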