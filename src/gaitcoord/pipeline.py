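"""End-to-end orchestration: signals -> angles -> cycles -> CRP -> statistics.

A run is described by a :class:`RunConfig` (validated against a strict
schema; unknown keys are rejected).  Synthetic mode draws a two-group
cohort from the shipped parameter sets; files mode reads raw IMU CSVs
listed in a cohort manifest.  All randomness flows from the single
top-level seed through spawned child generators, so a run is bit-for-bit
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coordination, cycles, imu_io, orientation, stats, synthetic
from .series import JointAngleSeries

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)

_SCHEMA: dict = {
    "mode": "synthetic",  # synthetic | files
    "seed": 0,
    "out_dir": None,
    "synthetic": {
        "emission": "kinematic",  # kinematic | raw
        "groups": ["PD", "HOA"],
        "n_participants": None,   # optional override applied to every group
        "passes_per_speed": None,
    },
    "input": {"manifest": None},
    "filter": {"cutoff_hz": 6.0, "order": 4},
    "fusion": {"gain": 0.02},
    "calibration": {"window_s": None},
    "events": {"prominence": 0.5, "positive_swing": True, "override_path": None},
    "crp": {"pad": None},
    "stats": {"alpha": 0.05, "n_perm": 1000, "iqr_metrics": ["marp_deg", "dp_deg"]},
    "figures": False,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _merge(schema: dict, given: dict, path: str = "") -> dict:
    out = {}
    for key, default in schema.items():
        if isinstance(default, dict):
            out[key] = _merge(default, given.get(key, {}) or {}, f"{path}{key}.")
        else:
            out[key] = given.get(key, default)
    unknown = set(given) - set(schema)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(path + k for k in sorted(unknown))}")
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration.  Build with :meth:`from_dict` or
    :meth:`from_yaml`; field access mirrors the schema nesting."""

    data: dict = field(default_factory=lambda: _merge(_SCHEMA, {}))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(_merge(_SCHEMA, d))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.data[key]

    def validate(self) -> None:
        d = self.data
        if d["mode"] not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if d["mode"] == "files" and not d["input"]["manifest"]:
            raise ValueError("files mode requires input.manifest")
        if d["synthetic"]["emission"] not in ("kinematic", "raw"):
            raise ValueError("synthetic.emission must be 'kinematic' or 'raw'")
        if not 0 < d["stats"]["alpha"] < 1:
            raise ValueError("stats.alpha must be in (0, 1)")
        if d["filter"]["cutoff_hz"] <= 0 or d["filter"]["order"] < 1:
            raise ValueError("invalid filter settings")


@dataclass
class _Pass:
    angles: JointAngleSeries
    event_signal: np.ndarray | None
    participant: str
    group: str
    speed: str
    pass_idx: int
    walking_speed_mps: float


def summarize_passes(
    pairs: list[tuple[_Pass, cycles.GaitEvents]], pad: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Participant x speed MARP/DP/excursion summaries from segmented passes.

    Pools gait cycles across a participant's passes at each speed, computes
    the CRP ensemble (mean and SD curves, MARP, DP) and mean excursions,
    and returns (summary table, per-participant curve table, total cycles).
    """
    per_key: dict[tuple, dict] = {}
    total_cycles = 0
    for p, ev in pairs:
        cyc = cycles.segment_and_normalize(p.angles, ev)
        crp_cycles = coordination.analyze_pass(p.angles, ev, pad=pad)
        total_cycles += cyc.n_cycles
        entry = per_key.setdefault(
            (p.participant, p.group, p.speed),
            {"crp": [], "hip_exc": [], "knee_exc": [], "speed": [], "n_cycles": 0},
        )
        entry["crp"].append(crp_cycles)
        entry["hip_exc"].append(cyc.hip_excursions_deg)
        entry["knee_exc"].append(cyc.knee_excursions_deg)
        entry["speed"].append(p.walking_speed_mps)
        entry["n_cycles"] += cyc.n_cycles

    rows, curve_rows = [], []
    for (pid, group, speed), entry in sorted(per_key.items()):
        ens = coordination.build_ensemble(
            entry["crp"], meta={"participant": pid, "group": group, "speed": speed}
        )
        rows.append(
            {
                "participant": pid,
                "group": group,
                "speed": speed,
                "marp_deg": ens.marp,
                "dp_deg": ens.dp,
                "hip_excursion_deg": float(np.mean(np.concatenate(entry["hip_exc"]))),
                "knee_excursion_deg": float(np.mean(np.concatenate(entry["knee_exc"]))),
                "walking_speed_mps": float(np.mean(entry["speed"])),
                "n_cycles": entry["n_cycles"],
            }
        )
        for metric, curve in (("marp", ens.mean_curve), ("dp", ens.sd_curve)):
            curve_rows.append(
                {"participant": pid, "group": group, "speed": speed, "metric": metric}
                | {f"node{i}": curve[i] for i in range(cycles.N_NODES)}
            )
    summary = pd.DataFrame(rows, columns=stats.SUMMARY_COLUMNS)
    return summary, pd.DataFrame(curve_rows), total_cycles


@dataclass
class PipelineResult:
    """Everything a run produced, in memory, plus where it was written."""

    summary: pd.DataFrame
    retained: pd.DataFrame
    exclusions: pd.DataFrame
    anova_speed: stats.AnovaReport
    ancova: dict[str, stats.AnovaReport]
    spm: dict[str, stats.SpmResult]
    curves: pd.DataFrame  # per participant x speed: mean and SD CRP curves
    counts: dict
    out_dir: Path | None = None


def _stage(name: str):
    """Decorator-ish context: re-raise stage failures with the stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def _collect_synthetic(cfg: RunConfig, seeds) -> list[_Pass]:
    syn = cfg["synthetic"]
    passes: list[_Pass] = []
    raw_mode = syn["emission"] == "raw"
    for group, child in zip(syn["groups"], seeds):
        overrides = {"seed": 0}
        if syn["n_participants"]:
            overrides["n_participants"] = syn["n_participants"]
        if syn["passes_per_speed"]:
            overrides["passes_per_speed"] = syn["passes_per_speed"]
        spec = synthetic.default_cohort_spec(group, **overrides)
        rng = np.random.default_rng(child)
        cohort = synthetic.generate_cohort(spec, rng, emission=syn["emission"])
        for cp in cohort:
            tr = cp.truth
            if raw_mode:
                angles, event_signal = _angles_from_raw(cfg, cp.raw)
            else:
                angles, event_signal = cp.angles, cp.shank_gyro
            passes.append(
                _Pass(
                    angles,
                    event_signal,
                    tr.participant,
                    tr.group,
                    tr.speed_condition,
                    tr.pass_index,
                    tr.walking_speed_mps,
                )
            )
    return passes


def _angles_from_raw(cfg: RunConfig, raw: dict[str, imu_io.ImuRecording]):
    filt = cfg["filter"]
    recs = {
        k: imu_io.lowpass_filter(r, filt["cutoff_hz"], filt["order"]) for k, r in raw.items()
    }
    gain = cfg["fusion"]["gain"]
    orient = {k: orientation.complementary_fuse(r, gain=gain) for k, r in recs.items()}
    angles = orientation.compute_joint_angles(
        orient["pelvis"],
        orient["thigh_r"],
        orient["shank_r"],
        calibration_window_s=cfg["calibration"]["window_s"],
    )
    return angles, recs["shank_r"].gyro[:, 2]


def _collect_files(cfg: RunConfig) -> list[_Pass]:
    manifest_path = Path(cfg["input"]["manifest"])
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    passes = []
    for _, row in manifest.iterrows():
        raw = {
            "pelvis": imu_io.read_imu_csv(base / row["pelvis_csv"], "pelvis"),
            "thigh_r": imu_io.read_imu_csv(base / row["thigh_csv"], "thigh_r"),
            "shank_r": imu_io.read_imu_csv(base / row["shank_csv"], "shank_r"),
        }
        angles, event_signal = _angles_from_raw(cfg, raw)
        passes.append(
            _Pass(
                angles,
                event_signal,
                str(row["participant"]),
                str(row["group"]),
                str(row["speed"]),
                int(row["pass_idx"]),
                float(row["walking_speed_mps"]),
            )
        )
    return passes


def _load_event_overrides(path: str | None) -> dict[tuple, np.ndarray]:
    if not path:
        return {}
    df = pd.read_csv(path)
    out = {}
    for (p, s, k), grp in df.groupby(["participant", "speed", "pass_idx"]):
        out[(str(p), str(s), int(k))] = np.sort(grp["ic_index"].to_numpy(dtype=int))
    return out


def run_pipeline(config: RunConfig | dict, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis chain and (optionally) write the report bundle.

    Stages: signal ingest -> (filter/fuse) joint angles -> gait events ->
    cycle segmentation + excursion -> CRP/MARP/DP -> outlier exclusion ->
    ANOVA / ANCOVAs / SPM.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    cfg = config
    out_dir = out_dir or cfg["out_dir"]

    seed_seq = np.random.SeedSequence(cfg["seed"])
    cohort_seeds = seed_seq.spawn(8)  # fixed pool: groups, SPM, spare

    with _stage("ingest"):
        if cfg["mode"] == "synthetic":
            passes = _collect_synthetic(cfg, cohort_seeds[:4])
        else:
            passes = _collect_files(cfg)
        if not passes:
            raise ValueError("no passes to analyse")

    ev_cfg = cfg["events"]
    overrides = _load_event_overrides(ev_cfg["override_path"])
    filt = cfg["filter"]

    with _stage("events"):
        pairs: list[tuple[_Pass, cycles.GaitEvents]] = []
        for p in passes:
            fs = p.angles.fs
            sig = imu_io.lowpass_filter(p.event_signal, filt["cutoff_hz"], filt["order"], fs=fs)
            ev = cycles.detect_initial_contacts(
                sig,
                fs,
                prominence=ev_cfg["prominence"],
                positive_swing=ev_cfg["positive_swing"],
                pass_id=f"{p.participant}/{p.speed}/p{p.pass_idx}",
            )
            key_ovr = (p.participant, p.speed, p.pass_idx)
            if key_ovr in overrides:
                ev = cycles.GaitEvents(overrides[key_ovr], ev.midswing_indices, ev.pass_id)
            if ev.n_cycles < 1:
                log.warning("%s: no cycles; pass skipped", ev.pass_id)
                continue
            pairs.append((p, ev))

    with _stage("cycles+crp"):
        summary, curves, total_cycles = summarize_passes(pairs, pad=cfg["crp"]["pad"])

    st = cfg["stats"]
    with _stage("outlier-exclusion"):
        retained, exclusions = stats.iqr_exclude(summary, tuple(st["iqr_metrics"]))

    with _stage("group-stats"):
        groups = sorted(retained["group"].unique())
        if len(groups) < 2:
            missing = {"HOA", "PD"} - set(groups)
            raise ValueError(
                f"empty design cell: group={'/'.join(sorted(missing)) or 'second group'}"
            )
        anova_speed = stats.two_way_anova(retained, "walking_speed_mps", alpha=st["alpha"])
        ancova = {
            resp: stats.two_way_ancova(retained, resp, alpha=st["alpha"])
            for resp in ("marp_deg", "dp_deg", "hip_excursion_deg", "knee_excursion_deg")
        }
        spm_rng = np.random.default_rng(cohort_seeds[4])
        kept = set(retained["participant"])
        spm_results: dict[str, stats.SpmResult] = {}
        for metric in ("marp", "dp"):
            for speed in sorted(retained["speed"].unique()):
                sel = curves[
                    (curves["metric"] == metric)
                    & (curves["speed"] == speed)
                    & curves["participant"].isin(kept)
                ]
                node_cols = [f"node{i}" for i in range(cycles.N_NODES)]
                wa = sel[sel["group"] == groups[0]][node_cols].to_numpy()
                wb = sel[sel["group"] == groups[1]][node_cols].to_numpy()
                spm_results[f"{metric}_{speed}"] = stats.spm_ttest2(
                    wa, wb, alpha=st["alpha"], n_perm=st["n_perm"], rng=spm_rng
                )

    counts = {
        "passes": len(passes),
        "cycles_retained": total_cycles,
        "participants": int(summary["participant"].nunique()),
        "participants_excluded": int(exclusions["participant"].nunique()),
        "spm_reference_order": f"t = {groups[0]} - {groups[1]}",
    }
    result = PipelineResult(
        summary, retained, exclusions, anova_speed, ancova, spm_results, curves, counts
    )
    if out_dir is not None:
        with _stage("report"):
            result.out_dir = _write_bundle(result, Path(out_dir), cfg)
    return result


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _report_dict(result: PipelineResult) -> dict:
    def anova_dict(rep: stats.AnovaReport) -> dict:
        return {
            "response": rep.response,
            "effects": [asdict(e) for e in rep.effects],
            "posthoc": rep.posthoc.to_dict(orient="records"),
        }

    return {
        "counts": result.counts,
        "anova_walking_speed": anova_dict(result.anova_speed),
        "ancova": {k: anova_dict(v) for k, v in result.ancova.items()},
        "spm": {
            k: {
                "t_star": v.t_star,
                "max_abs_t": float(np.max(np.abs(v.t))),
                "clusters_pct": [[int(a), int(b)] for a, b in v.clusters],
                "n_perm": v.n_perm,
                "alpha": v.alpha,
            }
            for k, v in result.spm.items()
        },
    }


def _write_bundle(result: PipelineResult, out_dir: Path, cfg: RunConfig) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    result.summary.to_csv(out_dir / "summary.csv", index=False, float_format=fmt)
    result.retained.to_csv(out_dir / "summary_retained.csv", index=False, float_format=fmt)
    result.exclusions.to_csv(out_dir / "exclusions.csv", index=False, float_format=fmt)
    result.curves.to_csv(out_dir / "crp_curves.csv", index=False, float_format=fmt)
    for key, spm in result.spm.items():
        pd.DataFrame(
            {"node": np.arange(len(spm.t)), "t": spm.t, "t_star": spm.t_star}
        ).to_csv(out_dir / f"spm_{key}.csv", index=False, float_format=fmt)
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(_report_dict(result), fh, indent=1)
    with open(out_dir / "report.txt", "w") as fh:
        fh.write(_text_report(result))
    if cfg["figures"]:
        _write_figures(result, out_dir)
    log.info("report bundle written to %s", out_dir)
    return out_dir


def _text_report(result: PipelineResult) -> str:
    lines = ["gaitcoord pipeline report", "=" * 26, ""]
    lines.append(f"passes: {result.counts['passes']}  cycles: {result.counts['cycles_retained']}")
    lines.append(
        f"participants: {result.counts['participants']} "
        f"(excluded: {result.counts['participants_excluded']})"
    )
    lines.append("")
    lines.append("Two-way ANOVA on walking speed:")
    for e in result.anova_speed.effects:
        lines.append(
            f"  {e.effect:12s} F({e.df_num},{e.df_den}) = {e.F:7.3f}  "
            f"p = {e.p:.4f}  partial eta2 = {e.partial_eta2:.3f}"
        )
    for resp, rep in result.ancova.items():
        lines.append(f"ANCOVA on {resp} (covariate: walking speed):")
        for e in rep.effects:
            lines.append(
                f"  {e.effect:12s} F({e.df_num},{e.df_den}) = {e.F:7.3f}  "
                f"p = {e.p:.4f}  partial eta2 = {e.partial_eta2:.3f}"
            )
    lines.append("")
    lines.append(f"SPM ({result.counts['spm_reference_order']}):")
    for key, spm in result.spm.items():
        cl = "; ".join(f"{a}-{b}%" for a, b in spm.clusters) or "none"
        lines.append(f"  {key:15s} t* = {spm.t_star:.3f}  supra-threshold clusters: {cl}")
    return "\n".join(lines) + "\n"


def _write_figures(result: PipelineResult, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    node_cols = [f"node{i}" for i in range(cycles.N_NODES)]
    speeds = sorted(result.retained["speed"].unique())
    groups = sorted(result.retained["group"].unique())
    colors = {groups[0]: "tab:red", groups[1]: "tab:blue"}
    x = np.arange(cycles.N_NODES)

    fig, axes = plt.subplots(2, len(speeds), figsize=(4 * len(speeds), 6), sharex=True)
    for i, metric in enumerate(("marp", "dp")):
        for j, speed in enumerate(speeds):
            ax = axes[i, j]
            for group in groups:
                sel = result.curves[
                    (result.curves["metric"] == metric)
                    & (result.curves["speed"] == speed)
                    & (result.curves["group"] == group)
                    & result.curves["participant"].isin(result.retained["participant"])
                ][node_cols].to_numpy()
                m, s = sel.mean(axis=0), sel.std(axis=0, ddof=1)
                ax.plot(x, m, color=colors[group], label=group)
                ax.fill_between(x, m - s, m + s, color=colors[group], alpha=0.2)
            ax.set_title(f"{metric.upper()} - {speed}")
            if i == 1:
                ax.set_xlabel("% gait cycle")
            if j == 0:
                ax.set_ylabel("degrees")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "fig_ensemble.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, len(speeds), figsize=(4 * len(speeds), 6), sharex=True)
    for i, metric in enumerate(("marp", "dp")):
        for j, speed in enumerate(speeds):
            ax = axes[i, j]
            spm = result.spm[f"{metric}_{speed}"]
            ax.plot(x, spm.t, color="black")
            ax.axhline(spm.t_star, color="red", linestyle="--")
            ax.axhline(-spm.t_star, color="red", linestyle="--")
            ax.set_title(f"SPM t: {metric.upper()} - {speed}")
            if i == 1:
                ax.set_xlabel("% gait cycle")
            if j == 0:
                ax.set_ylabel("t")
    fig.tight_layout()
    fig.savefig(out_dir / "fig_spm.png", dpi=120)
    plt.close(fig)
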