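"""Synthetic gait-cohort generator.

Emulates the cyclic sagittal hip/knee kinematics, shank angular-velocity
signatures, and raw IMU streams of older adults walking short straight
passes at slow / preferred / fast instructed speeds.  Group parameter sets
(walking speed, joint excursion, hip-knee phase lag, cadence) ship as YAML
files under ``gaitcoord/configs``.

The waveform model is deliberately simple so downstream coordination
metrics are analytically predictable: hip and knee are sinusoids at the
stride frequency, the knee lagging the hip by a per-cycle phase draw
lambda ~ Normal(mean lag, lag SD).  Lag transitions are cross-faded over
the first 5% of each cycle with a cosine ramp so the waveform (and hence
its Hilbert phase) stays smooth across cycle boundaries.  Every quantity
drawn is recorded in a truth object so recovery can be tested exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .imu_io import GRAVITY, ImuRecording, write_imu_csv
from .orientation import WORLD_MAG, WORLD_UP, qconj, qrotate
from .series import JointAngleSeries

__all__ = [
    "ConditionSpec",
    "CohortSpec",
    "PassTruth",
    "default_cohort_spec",
    "generate_pass",
    "generate_joint_waveforms",
    "generate_shank_gyro",
    "generate_raw_imu",
    "generate_cohort",
    "write_cohort",
    "SPEED_CONDITIONS",
]

log = logging.getLogger(__name__)

SPEED_CONDITIONS = ("slow", "preferred", "fast")

# hardware ranges used for clipping raw emissions
ACCEL_RANGE = 16.0 * GRAVITY          # +/- 16 g
GYRO_RANGE = np.deg2rad(2000.0)       # +/- 2000 deg/s
MAG_RANGE = 190.0                     # +/- 1.9 Gauss in uT

_FADE_FRACTION = 0.05                 # lag cross-fade, fraction of cycle
_SWING_CENTER = 0.8                   # mid-swing bump centre, cycle fraction
_SWING_WIDTH = 0.05                   # bump SD, cycle fraction
_SWING_PEAK = 5.0                     # rad/s, dominant mid-swing peak


@dataclass
class ConditionSpec:
    """Generative parameters for one speed condition."""

    speed_mean: float
    speed_sd: float
    hip_exc_mean: float
    hip_exc_sd: float
    knee_exc_mean: float
    knee_exc_sd: float
    lag_mean_deg: float
    lag_sd_deg: float
    cadence_spm: float
    strides_per_pass: int

    def __post_init__(self) -> None:
        if self.speed_mean <= 0:
            raise ValueError("walking speed mean must be positive")
        if self.hip_exc_mean <= 0 or self.knee_exc_mean <= 0:
            raise ValueError("joint excursions must be positive")
        if self.cadence_spm <= 0:
            raise ValueError("cadence must be positive")
        for sd in (self.speed_sd, self.hip_exc_sd, self.knee_exc_sd, self.lag_sd_deg):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.strides_per_pass < 1:
            raise ValueError("strides_per_pass must be >= 1")


@dataclass
class CohortSpec:
    """Full specification of one synthetic group cohort."""

    group: str
    n_participants: int
    conditions: dict[str, ConditionSpec]
    passes_per_speed: int = 5
    fs: float = 200.0
    accel_noise_sd: float = 0.05
    gyro_noise_sd: float = 0.005
    mag_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.passes_per_speed < 1:
            raise ValueError("passes_per_speed must be >= 1")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for sd in (self.accel_noise_sd, self.gyro_noise_sd, self.mag_noise_sd):
            if sd < 0:
                raise ValueError("noise SDs must be non-negative")
        fixed = {}
        for name, c in self.conditions.items():
            fixed[name] = c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
        self.conditions = fixed


@dataclass
class PassTruth:
    """Ground truth for one emitted pass (the oracle for recovery tests)."""

    participant: str
    group: str
    speed_condition: str
    pass_index: int
    fs: float
    samples_per_cycle: int
    n_cycles: int
    hip_excursion_deg: float
    knee_excursion_deg: float
    lags_deg: np.ndarray            # one drawn lag per cycle
    ic_indices: np.ndarray          # n_cycles + 1 boundaries, samples
    walking_speed_mps: float
    cadence_spm: float
    n_samples: int

    def __post_init__(self) -> None:
        self.lags_deg = np.asarray(self.lags_deg, dtype=float)
        self.ic_indices = np.asarray(self.ic_indices, dtype=int)
        if np.any(np.diff(self.ic_indices) <= 0):
            raise ValueError("truth IC indices must be strictly increasing")
        if len(self.ic_indices) != self.n_cycles + 1:
            raise ValueError("need n_cycles + 1 IC boundaries")
        if self.ic_indices[-1] >= self.n_samples:
            raise ValueError("IC indices exceed emitted signal length")


def default_cohort_spec(group: str, **overrides) -> CohortSpec:
    """Load the shipped parameter set for ``'PD'`` or ``'HOA'``.

    Keyword overrides replace top-level fields (e.g. ``seed=7``,
    ``n_participants=50``).
    """
    name = group.lower()
    if name not in ("pd", "hoa"):
        raise ValueError("group must be 'PD' or 'HOA'")
    text = resources.files("gaitcoord.configs").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    noise = raw.pop("noise")
    spec = CohortSpec(
        group=raw["group"],
        n_participants=raw["n_participants"],
        conditions={k: ConditionSpec(**v) for k, v in raw["conditions"].items()},
        passes_per_speed=raw["passes_per_speed"],
        fs=raw["fs"],
        accel_noise_sd=noise["accel_sd"],
        gyro_noise_sd=noise["gyro_sd"],
        mag_noise_sd=noise["mag_sd"],
        seed=raw["seed"],
    )
    for key, val in overrides.items():
        if not hasattr(spec, key):
            raise TypeError(f"unknown CohortSpec field {key!r}")
        setattr(spec, key, val)
    return spec


def _lag_profile(lags_rad: np.ndarray, samples_per_cycle: int, n_samples: int) -> np.ndarray:
    """Per-sample lag: constant within each cycle, cosine cross-fade over the
    first 5% of each cycle from the previous cycle's lag."""
    spc = samples_per_cycle
    u = np.arange(n_samples) / spc
    cycle = np.minimum(u.astype(int), len(lags_rad) - 1)
    lam = lags_rad[cycle]
    fade_len = max(int(round(_FADE_FRACTION * spc)), 1)
    for k in range(1, len(lags_rad)):
        start = k * spc
        stop = min(start + fade_len, n_samples)
        s = (np.arange(stop - start)) / fade_len
        ramp = 0.5 * (1.0 - np.cos(np.pi * s))
        lam[start:stop] = lags_rad[k - 1] + (lags_rad[k] - lags_rad[k - 1]) * ramp
    return lam


def generate_pass(
    condition: ConditionSpec,
    fs: float,
    rng: np.random.Generator,
    hip_excursion_deg: float | None = None,
    knee_excursion_deg: float | None = None,
    walking_speed_mps: float | None = None,
    n_cycles: int | None = None,
    meta: dict | None = None,
) -> tuple[JointAngleSeries, PassTruth]:
    """Emit one pass of hip/knee sinusoidal kinematics plus its truth.

    Hip = offset + (excursion/2) sin(2 pi u); knee = offset +
    (excursion/2) sin(2 pi u - lambda(u)) with u the cycle fraction and
    lambda redrawn per cycle from Normal(lag mean, lag SD).  True initial
    contacts sit on the cycle boundaries (exact sample indices, since the
    stride period is rounded to whole samples).
    """
    meta = dict(meta or {})
    n_cycles = n_cycles if n_cycles is not None else condition.strides_per_pass
    stride_s = 2.0 * 60.0 / condition.cadence_spm  # one gait cycle = two steps
    spc = int(round(fs * stride_s))
    if spc < 8:
        raise ValueError("cadence too high for the sampling rate")
    hip_exc = (
        hip_excursion_deg
        if hip_excursion_deg is not None
        else max(rng.normal(condition.hip_exc_mean, condition.hip_exc_sd), 5.0)
    )
    knee_exc = (
        knee_excursion_deg
        if knee_excursion_deg is not None
        else max(rng.normal(condition.knee_exc_mean, condition.knee_exc_sd), 5.0)
    )
    speed = (
        walking_speed_mps
        if walking_speed_mps is not None
        else max(rng.normal(condition.speed_mean, condition.speed_sd), 0.1)
    )
    lags_deg = rng.normal(condition.lag_mean_deg, condition.lag_sd_deg, size=n_cycles)

    n = n_cycles * spc + 1
    t = np.arange(n) / fs
    u = np.arange(n) / spc
    a_hip = hip_exc / 2.0
    a_knee = knee_exc / 2.0
    lam = _lag_profile(np.deg2rad(lags_deg), spc, n)
    hip = (a_hip - 10.0) + a_hip * np.sin(2.0 * np.pi * u)
    knee = (a_knee + 2.0) + a_knee * np.sin(2.0 * np.pi * u - lam)

    truth = PassTruth(
        participant=meta.get("participant", ""),
        group=meta.get("group", ""),
        speed_condition=meta.get("speed", ""),
        pass_index=meta.get("pass_idx", 0),
        fs=fs,
        samples_per_cycle=spc,
        n_cycles=n_cycles,
        hip_excursion_deg=float(hip_exc),
        knee_excursion_deg=float(knee_exc),
        lags_deg=lags_deg,
        ic_indices=np.arange(n_cycles + 1) * spc,
        walking_speed_mps=float(speed),
        cadence_spm=condition.cadence_spm,
        n_samples=n,
    )
    meta.setdefault("walking_speed_mps", float(speed))
    return JointAngleSeries(t, hip, knee, meta=meta), truth


def generate_joint_waveforms(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[list[JointAngleSeries], list[PassTruth]]:
    """Emit every pass of the cohort (all participants x speeds x passes).

    Excursions and walking speed are drawn once per participant x speed;
    the per-cycle phase lags are redrawn for every pass.  Identical seeds
    yield bit-identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    all_angles: list[JointAngleSeries] = []
    all_truth: list[PassTruth] = []
    for p in range(spec.n_participants):
        pid = f"{spec.group}{p:03d}"
        for cond_name in spec.conditions:
            cond = spec.conditions[cond_name]
            hip_exc = max(rng.normal(cond.hip_exc_mean, cond.hip_exc_sd), 5.0)
            knee_exc = max(rng.normal(cond.knee_exc_mean, cond.knee_exc_sd), 5.0)
            speed = max(rng.normal(cond.speed_mean, cond.speed_sd), 0.1)
            for k in range(spec.passes_per_speed):
                angles, truth = generate_pass(
                    cond,
                    spec.fs,
                    rng,
                    hip_excursion_deg=hip_exc,
                    knee_excursion_deg=knee_exc,
                    walking_speed_mps=speed,
                    meta={
                        "participant": pid,
                        "group": spec.group,
                        "speed": cond_name,
                        "pass_idx": k,
                    },
                )
                all_angles.append(angles)
                all_truth.append(truth)
    return all_angles, all_truth


def generate_shank_gyro(
    truth: PassTruth,
    spec: CohortSpec | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Sagittal shank angular-velocity signature for one pass (rad/s).

    One dominant positive Gaussian bump per cycle at 80% of the cycle
    (mid-swing), on a baseline chosen so the signal crosses zero exactly at
    every interior cycle boundary — the true initial contacts.  Optional
    additive Gaussian noise uses the cohort's gyro noise SD.
    """
    if noise_sd is None:
        noise_sd = spec.gyro_noise_sd if spec is not None else 0.0
    spc = truth.samples_per_cycle
    u = np.arange(truth.n_samples) / spc
    w = np.zeros_like(u)
    for k in range(truth.n_cycles):
        w += _SWING_PEAK * np.exp(-((u - (k + _SWING_CENTER)) ** 2) / (2.0 * _SWING_WIDTH**2))
    baseline = _SWING_PEAK * np.exp(-((1.0 - _SWING_CENTER) ** 2) / (2.0 * _SWING_WIDTH**2))
    w -= baseline
    if noise_sd > 0 and rng is not None:
        w = w + rng.normal(0.0, noise_sd, size=w.shape)
    return w


def _segment_quats(angle_deg: np.ndarray) -> np.ndarray:
    """Quaternions for a rotation about the world medio-lateral Z axis."""
    half = np.deg2rad(angle_deg) / 2.0
    q = np.zeros((len(angle_deg), 4))
    q[:, 0] = np.cos(half)
    q[:, 3] = np.sin(half)
    return q


def generate_raw_imu(
    angles: JointAngleSeries,
    spec: CohortSpec | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> dict[str, ImuRecording]:
    """Emit pelvis/thigh/shank raw IMU streams consistent with a pass.

    The pelvis holds the world orientation; the thigh is rotated about the
    medio-lateral axis by the hip angle and the shank by hip + knee.  Each
    sensor reads gravity rotated into its frame (specific force), the
    angular rate of its segment, and the reference magnetic field in its
    frame, plus optional Gaussian noise.  Values beyond the hardware
    ranges (+/-16 g, +/-2000 deg/s, +/-1.9 Gauss) are clipped with a
    warning.
    """
    t = angles.time
    fs = angles.fs
    seg_angles = {
        "pelvis": np.zeros(angles.n_samples),
        "thigh_r": angles.hip_deg,
        "shank_r": angles.hip_deg + angles.knee_deg,
    }
    grav_w = GRAVITY * WORLD_UP  # specific force of a static sensor, world frame
    out: dict[str, ImuRecording] = {}
    for placement, theta in seg_angles.items():
        q = _segment_quats(theta)  # sensor -> world
        qc = qconj(q)
        accel = qrotate(qc, np.broadcast_to(grav_w, (len(t), 3)))
        mag = qrotate(qc, np.broadcast_to(WORLD_MAG, (len(t), 3)))
        rate = np.gradient(np.deg2rad(theta), t)  # rotation about world Z == sensor Z
        gyro = np.zeros((len(t), 3))
        gyro[:, 2] = rate
        if noise and spec is not None and rng is not None:
            accel = accel + rng.normal(0.0, spec.accel_noise_sd, accel.shape)
            gyro = gyro + rng.normal(0.0, spec.gyro_noise_sd, gyro.shape)
            mag = mag + rng.normal(0.0, spec.mag_noise_sd, mag.shape)
        for arr, rng_max, name in (
            (accel, ACCEL_RANGE, "accel"),
            (gyro, GYRO_RANGE, "gyro"),
            (mag, MAG_RANGE, "mag"),
        ):
            if np.any(np.abs(arr) > rng_max):
                log.warning("%s %s exceeds hardware range; clipping", placement, name)
                np.clip(arr, -rng_max, rng_max, out=arr)
        out[placement] = ImuRecording(placement, fs, t, accel, gyro, mag)
    return out


@dataclass
class CohortPass:
    """One emitted pass: kinematics, event signal, truth, optional raw IMU."""

    angles: JointAngleSeries
    shank_gyro: np.ndarray
    truth: PassTruth
    raw: dict[str, ImuRecording] | None = None


def generate_cohort(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    emission: str = "kinematic",
) -> list[CohortPass]:
    """Generate the full cohort.  ``emission='raw'`` also attaches noisy raw
    IMU streams for every pass (slower; used for sensor-fusion runs)."""
    if emission not in ("kinematic", "raw"):
        raise ValueError("emission must be 'kinematic' or 'raw'")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    angles_list, truth_list = generate_joint_waveforms(spec, rng)
    passes = []
    for angles, truth in zip(angles_list, truth_list):
        gyro = generate_shank_gyro(truth, spec, rng)
        raw = generate_raw_imu(angles, spec, rng) if emission == "raw" else None
        passes.append(CohortPass(angles, gyro, truth, raw))
    return passes


def write_cohort(passes: list[CohortPass], out_dir: str | Path) -> Path:
    """Write raw IMU CSVs, a cohort manifest, and a truth JSON sidecar.

    Passes lacking raw streams get them emitted noise-free on the fly so a
    files-mode run can always be reconstructed from disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truths = []
    for cp in passes:
        tr = cp.truth
        stem = f"{tr.participant}_{tr.speed_condition}_p{tr.pass_index}"
        raw = cp.raw if cp.raw is not None else generate_raw_imu(cp.angles, noise=False)
        paths = {}
        for placement, rec in raw.items():
            fname = f"{stem}_{placement}.csv"
            write_imu_csv(rec, out_dir / fname)
            paths[placement] = fname
        rows.append(
            {
                "participant": tr.participant,
                "group": tr.group,
                "speed": tr.speed_condition,
                "pass_idx": tr.pass_index,
                "walking_speed_mps": tr.walking_speed_mps,
                "pelvis_csv": paths["pelvis"],
                "thigh_csv": paths["thigh_r"],
                "shank_csv": paths["shank_r"],
            }
        )
        d = asdict(tr)
        d["lags_deg"] = tr.lags_deg.tolist()
        d["ic_indices"] = tr.ic_indices.tolist()
        truths.append(d)
    import pandas as pd

    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=1)
    return manifest
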