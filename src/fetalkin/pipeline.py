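"""End-to-end orchestration: simulate -> [render -> track ->] kinematics
-> statistics -> report.

Three modes:

* ``simulate-poses`` — draw a study design and planted AMT targets,
  synthesize bout-structured trajectories hitting those targets, then
  recompute AMT from the trajectories and run the full analysis.  The
  report compares recovered percent contrasts with the planted truth.
* ``simulate-volumes`` — additionally render BOLD-like phantom volumes,
  train the heatmap tracker on a labelled subset of frames, and use the
  *predicted* poses for kinematics (the toy acquisition covers the
  first frames of each oxygen epoch).
* ``real-data`` — read pose CSVs, an epoch-schedule CSV and a design
  CSV from disk and run kinematics + statistics.

Every stage writes its intermediate artifact (CSV/JSON) into the run
directory; runs are deterministic given config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import recovery as recovery_mod
from .kinematics import (
    PoseTimeSeries,
    V_TH_DEFAULT,
    build_amt_table,
    read_pose_csv,
)
from .stats import ModelSpec, analyze
from .synthetic import (
    DesignConfig,
    EffectSpec,
    StudyDesign,
    generate_amt_table,
    generate_design,
    generate_pose_series,
    render_volumes,
    simulate_tracking_scene,
    study_effect_spec,
)
from .tracking import TrackerConfig, VolumeGrid, predict_keypoints, train_tracker

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "make_report",
    "designs_to_frame",
    "frame_to_designs",
    "effects_to_dict",
    "effects_from_dict",
]

log = logging.getLogger("fetalkin")


# ---------------------------------------------------------------------------
# config (YAML-serializable)
# ---------------------------------------------------------------------------


def effects_to_dict(effects: EffectSpec) -> dict:
    d = asdict(effects)
    d["interaction_effects"] = {
        name: {f"{w},{lv}": float(v) for (w, lv), v in terms.items()}
        for name, terms in effects.interaction_effects.items()
    }
    return d


def effects_from_dict(d: dict) -> EffectSpec:
    d = dict(d)
    inter = {}
    for name, terms in d.get("interaction_effects", {}).items():
        parsed = {}
        for key, v in terms.items():
            w, lv = key.split(",")
            parsed[(int(w), lv)] = float(v)
        inter[name] = parsed
    d["interaction_effects"] = inter
    return EffectSpec(**d)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate-poses"  # simulate-poses | simulate-volumes | real-data
    out_dir: str = "fetalkin_run"
    seed: int = 0
    n_subjects: int = 10
    v_th: float = V_TH_DEFAULT
    design: DesignConfig = field(default_factory=DesignConfig)
    effects: EffectSpec = field(default_factory=study_effect_spec)
    # toy runs are small; aliased GA-group levels merge with the
    # reference instead of aborting the run
    model: ModelSpec = field(default_factory=lambda: ModelSpec(on_singular="drop"))
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    # simulate-volumes scale
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    frames_per_epoch: int = 20
    n_label_frames: int = 40
    trajectory_dt: float = 3.0
    # real-data inputs
    poses_dir: str | None = None
    designs_csv: str | None = None
    schedule_csv: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate-poses", "simulate-volumes", "real-data"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["effects"] = effects_to_dict(self.effects)
        Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "effects" in d:
            d["effects"] = effects_from_dict(d["effects"])
        if "design" in d:
            dc = d["design"]
            for k in ("ga_range", "epoch_duration_range", "dt_range"):
                if k in dc:
                    dc[k] = tuple(dc[k])
            d["design"] = DesignConfig(**dc)
        if "model" in d:
            mc = d["model"]
            for k in ("fixed_factors", "report_pairwise"):
                if mc.get(k) is not None:
                    mc[k] = tuple(mc[k])
            if "interactions" in mc:
                mc["interactions"] = tuple(tuple(x) for x in mc["interactions"])
            d["model"] = ModelSpec(**mc)
        if "tracker" in d:
            d["tracker"] = TrackerConfig(**d["tracker"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    """Outputs and provenance of one run."""

    mode: str
    seed: int
    stage_counts: dict
    contrasts: pd.DataFrame
    amt_table: pd.DataFrame
    recovery: pd.DataFrame | None
    config_snapshot: dict
    artifacts: dict


# ---------------------------------------------------------------------------
# design CSV round trip
# ---------------------------------------------------------------------------


def designs_to_frame(designs: list[StudyDesign]) -> pd.DataFrame:
    rows = []
    for d in designs:
        durs = dict(d.epoch_schedule)
        rows.append(
            {
                "subject_id": d.subject_id,
                "scan_id": d.scan_id,
                "maternal_position": d.maternal_position,
                "parity": d.parity,
                "placental_position": d.placental_position,
                "fetal_sex": d.fetal_sex,
                "fetal_position": d.fetal_position,
                "ga_weeks": d.ga_weeks,
                "ga_group": d.ga_group,
                "normoxia_s": durs["normoxia"],
                "hyperoxia_s": durs["hyperoxia"],
            }
        )
    return pd.DataFrame(rows)


def frame_to_designs(df: pd.DataFrame) -> list[StudyDesign]:
    return [
        StudyDesign(
            subject_id=str(r.subject_id),
            scan_id=str(r.scan_id),
            maternal_position=r.maternal_position,
            parity=r.parity,
            placental_position=r.placental_position,
            fetal_sex=r.fetal_sex,
            fetal_position=r.fetal_position,
            ga_weeks=float(r.ga_weeks),
            epoch_schedule=(
                ("normoxia", float(r.normoxia_s)),
                ("hyperoxia", float(r.hyperoxia_s)),
            ),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _simulate_poses(config: RunConfig, designs, out: Path):
    """Plant per-joint AMT targets, synthesize trajectories hitting them."""
    targets = generate_amt_table(designs, config.effects, seed=config.seed)
    targets.to_csv(out / "amt_targets.csv", index=False)
    traj_seeds = np.random.SeedSequence([config.seed, 0x21]).generate_state(
        len(designs)
    ) % (2**31)
    poses = {}
    n_clipped = 0
    dt = config.trajectory_dt
    for i, d in enumerate(designs):
        per_cond: dict[str, dict[str, float]] = {}
        sub = targets[targets.scan_id == d.scan_id]
        for cond, start, end in d.epoch_windows():
            cap = int(round((end - start) / dt)) * dt - dt
            tgt = {}
            for r in sub[sub.oxygen == cond].itertuples(index=False):
                amt = min(float(r.amt_s), cap)
                n_clipped += amt < float(r.amt_s)
                tgt[r.keypoint] = amt
            per_cond[cond] = tgt
        poses[d.scan_id] = (
            generate_pose_series(
                per_cond, d.epoch_windows(), dt=dt, seed=int(traj_seeds[i])
            ),
            d.epoch_windows(),
        )
    if n_clipped:
        log.warning("clipped %d AMT targets to epoch capacity", n_clipped)
    return poses, {"amt_targets": len(targets), "clipped_targets": int(n_clipped)}


def _simulate_volumes(config: RunConfig, designs, out: Path):
    """Render phantoms, train the tracker, use predicted poses."""
    grid = VolumeGrid(shape=config.grid_shape)
    dt = config.trajectory_dt
    n_frames = 2 * config.frames_per_epoch
    scan_seeds = np.random.SeedSequence([config.seed, 0x33]).generate_state(
        2 * len(designs)
    ) % (2**31)
    rendered = {}
    for i, d in enumerate(designs):
        pose = simulate_tracking_scene(
            n_frames, grid=grid, dt=dt, seed=int(scan_seeds[2 * i])
        )
        vols, _ = render_volumes(pose, grid=grid, seed=int(scan_seeds[2 * i + 1]))
        rendered[d.scan_id] = (pose, vols)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x44]))
    all_frames = [(sid, f) for sid in sorted(rendered) for f in range(n_frames)]
    pick = rng.choice(
        len(all_frames), size=min(config.n_label_frames, len(all_frames)), replace=False
    )
    train_vols, train_truths = [], []
    for j in sorted(pick):
        sid, f = all_frames[j]
        train_vols.append(rendered[sid][1][f])
        train_truths.append(rendered[sid][0].positions[f])
    tracker, history = train_tracker(train_vols, train_truths, grid, config.tracker)
    pd.DataFrame(history).to_csv(out / "tracker_history.csv", index_label="epoch")

    poses = {}
    half = config.frames_per_epoch * dt
    schedule = (("normoxia", 0.0, half), ("hyperoxia", half, 2 * half))
    errors = []
    for sid, (pose_true, vols) in rendered.items():
        pred_pos = np.empty_like(pose_true.positions)
        for f in range(n_frames):
            pred = predict_keypoints(tracker, vols[f])
            pred_pos[f] = pred[["x_mm", "y_mm", "z_mm"]].to_numpy()
        errors.append(np.linalg.norm(pred_pos - pose_true.positions, axis=-1).mean())
        poses[sid] = (
            PoseTimeSeries(times=pose_true.times, positions=pred_pos),
            schedule,
        )
    counts = {
        "rendered_frames": n_frames * len(designs),
        "labelled_frames": len(train_vols),
        "mean_tracking_error_mm": float(np.mean(errors)),
    }
    return poses, counts


def _load_real_data(config: RunConfig):
    designs = frame_to_designs(pd.read_csv(config.designs_csv))
    sched = pd.read_csv(config.schedule_csv)
    poses = {}
    for d in designs:
        pose = read_pose_csv(Path(config.poses_dir) / f"{d.scan_id}.csv")
        rows = sched[sched.scan_id == d.scan_id]
        schedule = tuple(
            (r.condition, float(r.start_s), float(r.end_s))
            for r in rows.itertuples(index=False)
        )
        poses[d.scan_id] = (pose, schedule)
    return designs, poses


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured pipeline and write all artifacts.

    A stage failure raises with the failing stage named; artifacts
    written before the failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    counts: dict = {}
    stage = "design"
    try:
        if config.mode == "real-data":
            stage = "load"
            designs, poses = _load_real_data(config)
        else:
            designs = generate_design(
                config.n_subjects, seed=config.seed, config=config.design
            )
            designs_to_frame(designs).to_csv(out / "designs.csv", index=False)
            if config.mode == "simulate-poses":
                stage = "trajectories"
                poses, c = _simulate_poses(config, designs, out)
            else:
                stage = "volumes+tracking"
                poses, c = _simulate_volumes(config, designs, out)
            counts.update(c)
        counts["scans"] = len(designs)
        log.info("stage %s done: %d scans", stage, len(designs))

        stage = "kinematics"
        amt_table = build_amt_table(poses, designs, v_th=config.v_th)
        amt_table.to_csv(out / "amt_table.csv", index=False)
        counts["amt_rows"] = len(amt_table)
        counts["zero_amt_rows"] = int(amt_table.amt_s.eq(0).sum())
        log.info("kinematics done: %d rows", len(amt_table))

        stage = "statistics"
        fit, contrasts = analyze(amt_table, config.model)
        contrasts.to_csv(out / "contrasts.csv", index=False)
        counts["contrasts"] = len(contrasts)
        (out / "fit.json").write_text(
            json.dumps(
                {
                    "var_subject": fit.var_subject,
                    "var_scan_within_position": fit.var_scan_within_position,
                    "var_residual": fit.var_residual,
                    "robust_iterations": fit.iterations,
                    "converged": fit.converged,
                },
                indent=2,
            )
        )

        recovery = None
        if config.mode != "real-data":
            truth = recovery_mod.planted_percent(config.effects)
            recovery = contrasts.copy()
            recovery["planted_pct"] = [
                truth.get((e, c), np.nan)
                for e, c in zip(recovery.effect, recovery.contrast)
            ]
            recovery = recovery.dropna(subset=["planted_pct"])
            recovery.to_csv(out / "recovery.csv", index=False)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    snapshot = yaml.safe_load((out / "config.yaml").read_text())
    return RunReport(
        mode=config.mode,
        seed=config.seed,
        stage_counts=counts,
        contrasts=contrasts,
        amt_table=amt_table,
        recovery=recovery,
        config_snapshot=snapshot,
        artifacts={p.name: str(p) for p in sorted(out.iterdir())},
    )


def make_report(report: RunReport, out_path) -> Path:
    """Write a human-readable run summary (markdown + figures)."""
    if report.contrasts.empty:
        raise ValueError("empty contrast table")
    out_path = Path(out_path)
    out_path.mkdir(parents=True, exist_ok=True)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figures = []
    amt = report.amt_table
    if {"ga_group", "extremity", "amt_s"} <= set(amt.columns):
        fig, ax = plt.subplots(figsize=(6, 4))
        for ext, grp in amt.groupby("extremity"):
            m = grp.groupby("ga_group")["amt_s"].mean()
            ax.plot(m.index, m.values, marker="o", label=ext)
        ax.set_xlabel("gestational age group (weeks)")
        ax.set_ylabel("mean AMT (s)")
        ax.legend(title="extremity")
        fig.savefig(out_path / "amt_by_ga_extremity.png", dpi=100)
        plt.close(fig)
        figures.append("amt_by_ga_extremity.png")
    if {"oxygen", "amt_s"} <= set(amt.columns):
        fig, ax = plt.subplots(figsize=(4, 4))
        conds = sorted(amt.oxygen.unique())
        ax.boxplot([amt.loc[amt.oxygen == c, "amt_s"].to_numpy() for c in conds])
        ax.set_xticklabels(conds)
        ax.set_ylabel("AMT (s)")
        fig.savefig(out_path / "amt_by_oxygen.png", dpi=100)
        plt.close(fig)
        figures.append("amt_by_oxygen.png")
    if report.recovery is not None and len(report.recovery):
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(report.recovery.planted_pct, report.recovery.estimate_pct)
        lim = [
            float(min(report.recovery.planted_pct.min(), report.recovery.estimate_pct.min())),
            float(max(report.recovery.planted_pct.max(), report.recovery.estimate_pct.max())),
        ]
        ax.plot(lim, lim, ls="--", c="gray")
        ax.set_xlabel("planted effect (%)")
        ax.set_ylabel("recovered effect (%)")
        fig.savefig(out_path / "recovery_scatter.png", dpi=100)
        plt.close(fig)
        figures.append("recovery_scatter.png")

    lines = [
        "# fetalkin run report",
        "",
        f"- mode: {report.mode}",
        f"- seed: {report.seed}",
        f"- velocity threshold v_th: "
        f"{sorted(set(amt.v_th)) if 'v_th' in amt.columns else 'n/a'} mm/s",
        f"- frame interval dt per scan: "
        f"{sorted(set(round(float(x), 3) for x in amt.dt_s)) if 'dt_s' in amt.columns else 'n/a'} s",
        "",
        "## Stage counts",
        "",
    ]
    lines += [f"- {k}: {v}" for k, v in report.stage_counts.items()]
    lines += [
        "",
        "## Contrasts (percent scale)",
        "",
        "```",
        report.contrasts.round(4).to_string(index=False),
        "```",
        "",
    ]
    if figures:
        lines += ["## Figures", ""] + [f"![{f}]({f})" for f in figures]
    path = out_path / "report.md"
    path.write_text("\n".join(lines))
    return path
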