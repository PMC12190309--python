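"""Continuous relative phase (CRP) and its MARP / DP summaries.

CRP quantifies the instantaneous coupling of an adjacent joint pair: the
absolute difference of the joints' Hilbert phase angles, folded onto
[0, 180] degrees, where 0 is perfectly in-phase and 180 anti-phase
movement.  MARP (mean absolute relative phase) is the mean of the
ensemble-averaged CRP waveform; DP (deviation phase) is the mean of the
pointwise across-cycle standard deviation — a within-participant
coordination-variability summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .cycles import GaitEvents, N_NODES, normalize_cycles
from .series import JointAngleSeries

__all__ = [
    "PhaseSeries",
    "CrpEnsemble",
    "hilbert_phase",
    "crp",
    "marp_dp",
    "analyze_pass",
    "build_ensemble",
]

log = logging.getLogger(__name__)


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase (degrees) for one joint."""

    phase_deg: np.ndarray
    joint: str = ""

    def __post_init__(self) -> None:
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if not np.all(np.isfinite(self.phase_deg)):
            raise ValueError(f"{self.joint or 'phase'}: non-finite phase values")


@dataclass
class CrpEnsemble:
    """Per-cycle CRP waveforms with ensemble curves and scalar summaries.

    ``mean_curve`` / ``sd_curve`` are the pointwise across-cycle mean and
    sample SD over the 101 gait-cycle nodes; ``marp`` and ``dp`` are their
    respective means.  ``dp`` is NaN when fewer than two cycles exist.
    """

    cycles: np.ndarray  # (n_cycles, 101), degrees in [0, 180]
    meta: dict = field(default_factory=dict)
    mean_curve: np.ndarray = field(init=False)
    sd_curve: np.ndarray = field(init=False)
    marp: float = field(init=False)
    dp: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.cycles, dtype=float))
        if c.size == 0:
            raise ValueError("CrpEnsemble requires at least one cycle")
        if c.shape[1] != N_NODES:
            raise ValueError(f"CRP cycles must have {N_NODES} nodes")
        if c.min() < -1e-9 or c.max() > 180.0 + 1e-9:
            raise ValueError("CRP values must lie in [0, 180] degrees")
        self.cycles = c
        self.mean_curve = c.mean(axis=0)
        if c.shape[0] >= 2:
            self.sd_curve = c.std(axis=0, ddof=1)
            self.dp = float(self.sd_curve.mean())
        else:
            log.warning("single CRP cycle: DP undefined")
            self.sd_curve = np.full(N_NODES, np.nan)
            self.dp = float("nan")
        self.marp = float(self.mean_curve.mean())

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]


def hilbert_phase(
    x: np.ndarray, pad: int = 0, joint: str = "signal", mode: str = "periodic"
) -> PhaseSeries:
    """Instantaneous phase of an oscillatory series via the analytic signal.

    The series is centred by removing (max + min)/2 over the analysis
    span, extended by ``pad`` samples of surrogate data on each side
    (standing in for extraneous recording kept around the analysis span
    when no real neighbours exist), the analytic signal is formed, and the
    phase ``atan2(imag, real)`` is unwrapped and returned in degrees with
    the pad removed.

    ``mode='periodic'`` (default) wraps the leading/trailing ``pad``
    samples around, the natural continuation of a quasi-periodic gait
    signal when ``pad`` is one cycle length; ``mode='mirror'`` uses odd
    reflection about the endpoints, appropriate for non-periodic signals
    (note it reverses the local phase direction and is less accurate near
    an endpoint that sits on an extremum).

    Raises on an all-constant signal, whose phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= 2 * pad:
        raise ValueError(f"{joint}: series length {len(x)} must exceed twice the pad ({pad})")
    if np.ptp(x) == 0.0:
        raise ValueError(f"{joint}: constant signal has undefined phase")
    xc = x - 0.5 * (x.max() + x.min())
    if pad > 0:
        if mode == "periodic":
            left = xc[:pad]
            right = xc[-pad:]
        elif mode == "mirror":
            left = 2.0 * xc[0] - xc[pad:0:-1]
            right = 2.0 * xc[-1] - xc[-2:-pad - 2:-1]
        else:
            raise ValueError(f"unknown pad mode {mode!r}")
        padded = np.concatenate([left, xc, right])
    else:
        padded = xc
    analytic = hilbert(padded)
    phase = np.unwrap(np.angle(analytic))
    if pad > 0:
        phase = phase[pad:-pad]
    return PhaseSeries(np.rad2deg(phase), joint)


def crp(hip_phase: PhaseSeries, knee_phase: PhaseSeries) -> np.ndarray:
    """Continuous relative phase in degrees, folded onto [0, 180].

    The absolute hip-knee phase difference is taken modulo 360 and
    reflected about 180 so that 0 = in-phase and 180 = anti-phase.
    Symmetric in its arguments.
    """
    a = hip_phase.phase_deg
    b = knee_phase.phase_deg
    if len(a) != len(b):
        raise ValueError(f"phase length mismatch: {len(a)} vs {len(b)}")
    d = np.abs(a - b) % 360.0
    return np.where(d <= 180.0, d, 360.0 - d)


def marp_dp(crp_cycles: np.ndarray) -> tuple[float, float]:
    """(MARP, DP) from a stack of 101-node CRP cycles.

    MARP is the mean over nodes of the across-cycle mean; DP the mean over
    nodes of the across-cycle sample SD (n-1 denominator), NaN for a
    single cycle.
    """
    ens = CrpEnsemble(crp_cycles)
    return ens.marp, ens.dp


def crp_series_for_pass(angles: JointAngleSeries, pad: int) -> np.ndarray:
    """CRP over an entire pass: Hilbert phases of hip and knee, then folded
    difference — computed on the continuous waveform before segmentation."""
    hp = hilbert_phase(angles.hip_deg, pad=pad, joint="hip")
    kp = hilbert_phase(angles.knee_deg, pad=pad, joint="knee")
    return crp(hp, kp)


def analyze_pass(
    angles: JointAngleSeries,
    events: GaitEvents,
    pad: int | None = None,
) -> np.ndarray:
    """Per-cycle 101-node CRP waveforms for one pass, shape (n_cycles, 101).

    CRP is computed on the full continuous pass and only then segmented at
    the initial contacts and time-normalised.  The Hilbert pad defaults to
    one median cycle length of mirrored data on each side.
    """
    if events.n_cycles < 1:
        return np.empty((0, N_NODES))
    if pad is None:
        pad = int(np.median(np.diff(events.ic_indices)))
        pad = min(pad, angles.n_samples // 2 - 1)
    series = crp_series_for_pass(angles, pad)
    cycles, _, _ = normalize_cycles(series, events.ic_indices, angles.fs)
    return cycles


def build_ensemble(cycle_stacks: list[np.ndarray], meta: dict | None = None) -> CrpEnsemble:
    """Pool per-pass CRP cycle stacks into one participant-level ensemble."""
    stacks = [s for s in cycle_stacks if s.size]
    if not stacks:
        raise ValueError("no CRP cycles to pool")
    return CrpEnsemble(np.vstack(stacks), meta=meta or {})
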