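"""Shared time-series container for sagittal joint-angle waveforms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["JointAngleSeries"]


@dataclass
class JointAngleSeries:
    """Sagittal hip and knee angle waveforms on a shared time base.

    Angles are in degrees, flexion positive.  ``meta`` carries free-form
    labels (participant, speed condition, pass index) through the pipeline.
    """

    time: np.ndarray
    hip_deg: np.ndarray
    knee_deg: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hip_deg = np.asarray(self.hip_deg, dtype=float)
        self.knee_deg = np.asarray(self.knee_deg, dtype=float)
        n = len(self.time)
        if len(self.hip_deg) != n or len(self.knee_deg) != n:
            raise ValueError("time, hip_deg and knee_deg must have equal length")
        if not (np.all(np.isfinite(self.hip_deg)) and np.all(np.isfinite(self.knee_deg))):
            raise ValueError("joint angles must be finite")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz (time base is assumed uniform)."""
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def n_samples(self) -> int:
        return len(self.time)
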