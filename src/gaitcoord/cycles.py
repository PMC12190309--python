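"""Gait-event detection, cycle segmentation, time normalisation, excursion.

Initial contacts (IC) are found as the first negative-going zero-crossing
of the sagittal shank angular velocity after each mid-swing peak.  Cycles
span consecutive ICs and are resampled onto 101 evenly spaced points
(0-100% of the gait cycle, both endpoints included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .series import JointAngleSeries

__all__ = [
    "GaitEvents",
    "GaitCycleSet",
    "detect_initial_contacts",
    "segment_and_normalize",
    "normalize_cycles",
    "joint_excursion",
    "N_NODES",
    "MIN_CYCLE_S",
    "MAX_CYCLE_S",
]

log = logging.getLogger(__name__)

N_NODES = 101
MIN_CYCLE_S = 0.4   # physiological gate replacing visual inspection
MAX_CYCLE_S = 2.5


@dataclass
class GaitEvents:
    """Initial-contact and mid-swing peak sample indices for one pass."""

    ic_indices: np.ndarray
    midswing_indices: np.ndarray
    pass_id: str = ""

    def __post_init__(self) -> None:
        self.ic_indices = np.asarray(self.ic_indices, dtype=int)
        self.midswing_indices = np.asarray(self.midswing_indices, dtype=int)
        if np.any(np.diff(self.ic_indices) <= 0):
            raise ValueError("initial-contact indices must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return max(len(self.ic_indices) - 1, 0)


@dataclass
class GaitCycleSet:
    """Time-normalised hip/knee cycle waveforms with durations and excursions.

    ``hip_cycles`` and ``knee_cycles`` have shape (n_cycles, 101); the
    excursions are max - min of each cycle's *unnormalised* waveform.
    """

    hip_cycles: np.ndarray
    knee_cycles: np.ndarray
    durations_s: np.ndarray
    hip_excursions_deg: np.ndarray
    knee_excursions_deg: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("hip_cycles", "knee_cycles"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if arr.size and arr.shape[1] != N_NODES:
                raise ValueError(f"{name} must have {N_NODES} nodes per cycle")
            setattr(self, name, arr)
        if np.any(np.asarray(self.durations_s) <= 0):
            raise ValueError("cycle durations must be positive")

    @property
    def n_cycles(self) -> int:
        return 0 if self.hip_cycles.size == 0 else self.hip_cycles.shape[0]


def detect_initial_contacts(
    shank_gyro_sagittal: np.ndarray,
    fs: float,
    prominence: float = 0.5,
    positive_swing: bool = True,
    pass_id: str = "",
) -> GaitEvents:
    """Detect initial contacts from sagittal shank angular velocity.

    Mid-swing peaks are local maxima whose prominence exceeds
    ``prominence`` (rad/s); the IC after each peak is the first
    negative-going zero-crossing, rounded to the nearest sample.  Set
    ``positive_swing=False`` for a mounting convention in which the
    mid-swing peak is negative (the signal is sign-flipped internally).
    """
    from scipy.signal import find_peaks

    w = np.asarray(shank_gyro_sagittal, dtype=float)
    if not positive_swing:
        w = -w
    peaks, _ = find_peaks(w, prominence=prominence)
    if len(peaks) == 0:
        log.warning("%s: no mid-swing peaks found; returning empty events", pass_id or "pass")
        return GaitEvents(np.array([], dtype=int), np.array([], dtype=int), pass_id)

    ics = []
    kept_peaks = []
    for p in peaks:
        after = w[p:]
        below = np.nonzero(after <= 0.0)[0]
        if len(below) == 0:
            log.info("%s: peak at sample %d has no subsequent zero-crossing; dropped", pass_id, p)
            continue
        i = p + below[0]
        if i > p and w[i] < 0.0 < w[i - 1]:
            # sub-sample crossing between i-1 and i; round to nearest sample
            frac = w[i - 1] / (w[i - 1] - w[i])
            i = i - 1 + int(round(frac))
        ics.append(i)
        kept_peaks.append(p)
    # distinct, sorted events (two peaks can map to one crossing)
    ic_arr, first = np.unique(np.asarray(ics, dtype=int), return_index=True)
    peak_arr = np.asarray(kept_peaks, dtype=int)[first]
    return GaitEvents(ic_arr, peak_arr, pass_id)


def normalize_cycles(
    x: np.ndarray,
    ic_indices: np.ndarray,
    fs: float,
    min_duration_s: float = MIN_CYCLE_S,
    max_duration_s: float = MAX_CYCLE_S,
):
    """Resample each IC-to-IC span of a 1-D series onto 101 nodes.

    Returns ``(cycles, durations, spans)`` where ``cycles`` is
    (n_kept, 101), and ``spans`` the (start, stop) sample indices of kept
    cycles.  Cycles outside the duration gate are discarded and logged.
    """
    x = np.asarray(x, dtype=float)
    ics = np.asarray(ic_indices, dtype=int)
    cycles, durations, spans = [], [], []
    idx = np.arange(len(x))
    for i0, i1 in zip(ics[:-1], ics[1:]):
        dur = (i1 - i0) / fs
        if not (min_duration_s <= dur <= max_duration_s):
            log.info("cycle [%d, %d) duration %.3f s outside gate; discarded", i0, i1, dur)
            continue
        grid = np.linspace(i0, i1, N_NODES)
        cycles.append(np.interp(grid, idx, x))
        durations.append(dur)
        spans.append((int(i0), int(i1)))
    if not cycles:
        return np.empty((0, N_NODES)), np.array([]), []
    return np.vstack(cycles), np.asarray(durations), spans


def segment_and_normalize(
    angles: JointAngleSeries,
    events: GaitEvents,
    min_duration_s: float = MIN_CYCLE_S,
    max_duration_s: float = MAX_CYCLE_S,
) -> GaitCycleSet:
    """Cut a pass into gait cycles and time-normalise hip/knee waveforms.

    Fewer than two ICs yields an empty set.  Per-cycle excursions are
    computed on the unnormalised samples of each cycle span.
    """
    fs = angles.fs
    if events.n_cycles < 1:
        return GaitCycleSet(
            np.empty((0, N_NODES)), np.empty((0, N_NODES)),
            np.array([]), np.array([]), np.array([]), meta=dict(angles.meta),
        )
    hip, durations, spans = normalize_cycles(
        angles.hip_deg, events.ic_indices, fs, min_duration_s, max_duration_s
    )
    knee, _, _ = normalize_cycles(
        angles.knee_deg, events.ic_indices, fs, min_duration_s, max_duration_s
    )
    hip_exc = np.array([np.ptp(angles.hip_deg[i0:i1]) for i0, i1 in spans])
    knee_exc = np.array([np.ptp(angles.knee_deg[i0:i1]) for i0, i1 in spans])
    return GaitCycleSet(hip, knee, durations, hip_exc, knee_exc, meta=dict(angles.meta))


def joint_excursion(cycles: GaitCycleSet) -> tuple[float, float]:
    """Mean (hip, knee) excursion in degrees across all cycles of a set.

    An empty set yields ``(nan, nan)`` with a warning; downstream code
    treats NaN summaries as excluded.
    """
    if cycles.n_cycles == 0:
        log.warning("joint_excursion: empty cycle set; result undefined")
        return (float("nan"), float("nan"))
    return (float(np.mean(cycles.hip_excursions_deg)), float(np.mean(cycles.knee_excursions_deg)))
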