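"""Reading, writing, unit conversion, and low-pass filtering of IMU recordings.

The on-disk dialect is a plain CSV with one header row and columns
``time_s, ax, ay, az, gx, gy, gz, mx, my, mz``.  SI units are assumed
(m/s^2, rad/s, uT) unless a leading comment line ``# units: native``
declares the sensor's native units (g, deg/s, Gauss), in which case the
reader converts on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ImuRecording",
    "FormatError",
    "read_imu_csv",
    "write_imu_csv",
    "lowpass_filter",
    "GRAVITY",
    "PLACEMENTS",
]

log = logging.getLogger(__name__)

GRAVITY = 9.80665  # standard gravity, m/s^2 per g
GAUSS_TO_UT = 100.0

PLACEMENTS = ("pelvis", "thigh_r", "shank_r", "foot_r", "other")

_COLUMNS = ["time_s", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


class FormatError(ValueError):
    """Raised when an IMU CSV does not conform to the documented dialect."""


@dataclass
class ImuRecording:
    """One sensor's time-synchronised accelerometer/gyroscope/magnetometer streams.

    Attributes
    ----------
    placement : str
        Body placement label, one of :data:`PLACEMENTS`.
    fs : float
        Sampling rate in Hz.
    time : ndarray, shape (n,)
        Sample times in seconds, strictly increasing and uniform.
    accel : ndarray, shape (n, 3)
        Specific force in m/s^2 (a static, level sensor reads +g on its
        vertical axis).
    gyro : ndarray, shape (n, 3)
        Angular velocity in rad/s.
    mag : ndarray, shape (n, 3)
        Magnetic field in uT.
    """

    placement: str
    fs: float
    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}; expected one of {PLACEMENTS}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.time)
        for name in ("accel", "gyro", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            setattr(self, name, arr)
        self.time = np.asarray(self.time, dtype=float)
        _check_uniform_time(self.time, self.fs)

    @property
    def n_samples(self) -> int:
        return len(self.time)


def _check_uniform_time(t: np.ndarray, fs: float) -> None:
    if len(t) < 2:
        return
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time vector must be strictly increasing")
    nominal = 1.0 / fs
    if np.any(np.abs(dt - nominal) > 0.01 * nominal):
        raise ValueError("time vector is non-uniform (jitter exceeds 1% of the sample period)")


def read_imu_csv(path: str | Path, placement: str) -> ImuRecording:
    """Read one sensor stream from a CSV file in the documented dialect.

    A leading comment line ``# units: native`` triggers conversion from the
    sensor's native units (accel in g, gyro in deg/s, mag in Gauss) to SI
    (m/s^2, rad/s, uT).  Without that line the file is taken to already be
    in SI units.
    """
    path = Path(path)
    native_units = False
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if "units" in line and "native" in line:
                    native_units = True
            else:
                break
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {', '.join(missing)}")

    time = df["time_s"].to_numpy(dtype=float)
    if len(time) < 2:
        raise FormatError(f"{path.name}: need at least 2 samples")
    fs = 1.0 / np.median(np.diff(time))
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    mag = df[["mx", "my", "mz"]].to_numpy(dtype=float)
    if native_units:
        accel = accel * GRAVITY
        gyro = np.deg2rad(gyro)
        mag = mag * GAUSS_TO_UT
    try:
        return ImuRecording(placement, fs, time, accel, gyro, mag)
    except ValueError as exc:
        raise FormatError(f"{path.name}: {exc}") from exc


def write_imu_csv(recording: ImuRecording, path: str | Path) -> None:
    """Write a recording to CSV in SI units using the documented dialect."""
    df = pd.DataFrame(
        np.column_stack([recording.time, recording.accel, recording.gyro, recording.mag]),
        columns=_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


def lowpass_filter(x, cutoff_hz: float = 6.0, order: int = 4, fs: float | None = None):
    """Zero-phase low-pass Butterworth filter.

    Each channel is filtered forward and backward (``filtfilt``) with a
    Butterworth design of the given order, so the net response is
    zero-phase with the squared magnitude of the single-pass design (the
    -3 dB design cutoff becomes the -6 dB point of the net filter).

    Parameters
    ----------
    x : ImuRecording or ndarray
        Recording (all nine channels filtered) or array whose first axis is
        time.  For a bare array ``fs`` must be supplied.
    cutoff_hz : float
        Design cutoff frequency in Hz.  Must be below the Nyquist rate.
    order : int
        Design order per pass.
    fs : float, optional
        Sampling rate; taken from the recording when ``x`` is one.

    Returns
    -------
    Same type as ``x``, same length.
    """
    if isinstance(x, ImuRecording):
        fs = x.fs
        _validate_filter(cutoff_hz, order, fs, x.n_samples)
        sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
        return replace(
            x,
            accel=signal.sosfiltfilt(sos, x.accel, axis=0),
            gyro=signal.sosfiltfilt(sos, x.gyro, axis=0),
            mag=signal.sosfiltfilt(sos, x.mag, axis=0),
        )
    arr = np.asarray(x, dtype=float)
    if fs is None:
        raise ValueError("fs is required when filtering a bare array")
    _validate_filter(cutoff_hz, order, fs, arr.shape[0])
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, arr, axis=0)


def _validate_filter(cutoff_hz: float, order: int, fs: float, n: int) -> None:
    nyq = fs / 2.0
    if cutoff_hz <= 0:
        raise ValueError("cutoff frequency must be positive")
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {nyq} Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if n <= 3 * order:
        raise ValueError(f"signal length {n} too short for order-{order} zero-phase filtering")
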