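"""Velocity and absolute-movement-time (AMT) kinematics.

A keypoint trajectory sampled at an effective interval ``dt`` yields a
per-interval speed

    v_i = || p_{i+1} - p_i ||_2 / dt

and the absolute movement time of the keypoint over the series is

    AMT = dt * #{ i : v_i > v_th }

i.e. the total time during which the keypoint moves faster than the
threshold ``v_th``.  The default threshold is 3 mm/s (one in-plane voxel
per second on a 3 mm grid).  The inequality is strict: an interval at
exactly ``v_th`` does not count as movement.

Scans are split into oxygen epochs (normoxia, then hyperoxia) before AMT
is computed; the single inter-frame interval that straddles an epoch
boundary is discarded rather than prorated, so no interval mixes the two
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .keypoints import KEYPOINTS, joint_descriptor

__all__ = [
    "V_TH_DEFAULT",
    "PoseTimeSeries",
    "VelocitySeries",
    "MovementMask",
    "compute_velocity",
    "compute_amt",
    "movement_mask",
    "split_by_epoch",
    "build_amt_table",
    "read_pose_csv",
    "write_pose_csv",
]

#: Default movement threshold, mm/s (one 3 mm voxel per second).
V_TH_DEFAULT = 3.0

#: Relative tolerance on timestamp uniformity; the effective frame
#: interval is treated as constant per scan.
_DT_RTOL = 0.01


@dataclass
class PoseTimeSeries:
    """Keypoint trajectories for one scan (or scan segment).

    Parameters
    ----------
    times:
        Frame timestamps in seconds, strictly increasing and uniform to
        within 1%.
    positions:
        Array of shape ``(n_frames, n_keypoints, 3)``, mm.
    keypoints:
        Keypoint names, one per trajectory column.
    """

    times: np.ndarray
    positions: np.ndarray
    keypoints: tuple[str, ...] = KEYPOINTS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if self.positions.shape != (len(self.times), len(self.keypoints), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.times)} frames x {len(self.keypoints)} keypoints x 3"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in pose series")
        diffs = np.diff(self.times)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("times must be strictly increasing")
        if len(diffs):
            dt = float(np.median(diffs))
            if np.any(np.abs(diffs - dt) > _DT_RTOL * dt):
                raise ValueError(
                    "timestamps deviate from uniform spacing by more than "
                    f"{_DT_RTOL:.0%}; the effective dt must be constant per scan"
                )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt_effective(self) -> float:
        if len(self.times) < 2:
            raise ValueError("dt undefined for a single frame")
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class VelocitySeries:
    """Per-interval speeds, mm/s; shape ``(n_frames - 1, n_keypoints)``."""

    speeds: np.ndarray
    dt: float
    keypoints: tuple[str, ...] = KEYPOINTS

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.speeds.ndim == 1:
            self.speeds = self.speeds[:, None]
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class MovementMask:
    """Boolean movement indicator per interval and keypoint."""

    moving: np.ndarray
    v_th: float


def compute_velocity(pose: PoseTimeSeries) -> VelocitySeries:
    """Speed of every keypoint over every inter-frame interval.

    Forward difference: interval ``i`` spans frames ``i`` and ``i+1`` and
    its speed is attributed to interval ``i``.  No smoothing is applied.
    """
    if pose.n_frames < 2:
        raise ValueError("at least two frames are required")
    dt = pose.dt_effective
    disp = np.diff(pose.positions, axis=0)  # (n-1, k, 3)
    speeds = np.linalg.norm(disp, axis=2) / dt
    return VelocitySeries(speeds=speeds, dt=dt, keypoints=pose.keypoints)


def movement_mask(vel: VelocitySeries, v_th: float = V_TH_DEFAULT) -> MovementMask:
    """Strict-threshold movement indicator: moving iff ``v > v_th``."""
    if v_th < 0:
        raise ValueError("threshold must be non-negative")
    return MovementMask(moving=vel.speeds > v_th, v_th=v_th)


def compute_amt(vel: VelocitySeries, v_th: float = V_TH_DEFAULT) -> np.ndarray:
    """Absolute movement time in seconds, one value per keypoint.

    ``AMT = dt * #{i : v_i > v_th}``; always an integer multiple of
    ``dt`` and bounded by ``(n_frames - 1) * dt``.
    """
    mask = movement_mask(vel, v_th)
    return vel.dt * mask.moving.sum(axis=0).astype(float)


def split_by_epoch(
    pose: PoseTimeSeries,
    schedule: Sequence[tuple[str, float, float]],
) -> dict[str, PoseTimeSeries]:
    """Partition a scan into condition epochs by frame timestamp.

    Parameters
    ----------
    schedule:
        ``(condition, start_s, end_s)`` triples; epochs must be ordered
        and non-overlapping.  A frame belongs to the epoch whose
        half-open window ``[start, end)`` contains its timestamp; the
        final epoch is closed on the right.  Because velocities are then
        computed within each epoch separately, the interval straddling a
        boundary never contributes to any epoch's AMT.
    """
    prev_end = -np.inf
    for cond, start, end in schedule:
        if end <= start:
            raise ValueError(f"epoch {cond!r} has non-positive duration")
        if start < prev_end:
            raise ValueError("epochs overlap or are out of order")
        prev_end = end
    out: dict[str, PoseTimeSeries] = {}
    last = len(schedule) - 1
    for j, (cond, start, end) in enumerate(schedule):
        if j == last:
            sel = (pose.times >= start) & (pose.times <= end)
        else:
            sel = (pose.times >= start) & (pose.times < end)
        if not sel.any():
            continue
        out[cond] = PoseTimeSeries(
            times=pose.times[sel],
            positions=pose.positions[sel],
            keypoints=pose.keypoints,
        )
    return out


def build_amt_table(
    poses: Mapping[str, tuple[PoseTimeSeries, Sequence[tuple[str, float, float]]]],
    designs: Iterable,
    v_th: float = V_TH_DEFAULT,
) -> pd.DataFrame:
    """Join kinematics to study covariates: one row per scan x epoch x joint.

    Parameters
    ----------
    poses:
        Mapping scan_id -> (pose series, epoch schedule).
    designs:
        :class:`~fetalkin.synthetic.StudyDesign` records (one per scan).

    Returns
    -------
    DataFrame with design covariates, joint descriptors, ``amt_s``,
    ``n_intervals``, ``dt_s`` and ``epoch_duration_s`` per row.
    """
    design_by_scan = {d.scan_id: d for d in designs}
    missing = set(poses) - set(design_by_scan)
    if missing:
        raise KeyError(f"scans without design rows: {sorted(missing)}")
    extra = set(design_by_scan) - set(poses)
    if extra:
        raise KeyError(f"design rows without poses: {sorted(extra)}")

    rows = []
    for scan_id in sorted(poses):
        pose, schedule = poses[scan_id]
        d = design_by_scan[scan_id]
        epochs = split_by_epoch(pose, schedule)
        for cond, _, _ in schedule:
            if cond not in epochs:
                continue
            seg = epochs[cond]
            if seg.n_frames < 2:
                continue
            vel = compute_velocity(seg)
            amt = compute_amt(vel, v_th)
            n_int = seg.n_frames - 1
            for k, name in enumerate(seg.keypoints):
                jd = joint_descriptor(name)
                rows.append(
                    {
                        "subject_id": d.subject_id,
                        "scan_id": d.scan_id,
                        "maternal_position": d.maternal_position,
                        "parity": d.parity,
                        "oxygen": cond,
                        "placental_position": d.placental_position,
                        "fetal_position": d.fetal_position,
                        "fetal_sex": d.fetal_sex,
                        "ga_weeks": d.ga_weeks,
                        "ga_group": d.ga_group,
                        "keypoint": name,
                        "distance_class": jd.distance_class,
                        "extremity": jd.extremity,
                        "side": jd.side,
                        "amt_s": float(amt[k]),
                        "n_intervals": n_int,
                        "dt_s": seg.dt_effective,
                        "epoch_duration_s": seg.duration,
                        "v_th": v_th,
                    }
                )
    return pd.DataFrame(rows)


def write_pose_csv(path, pose: PoseTimeSeries) -> None:
    """Write a pose series as long-format CSV (frame, time, keypoint, xyz mm)."""
    recs = []
    for i, t in enumerate(pose.times):
        for k, name in enumerate(pose.keypoints):
            x, y, z = pose.positions[i, k]
            recs.append((i, t, name, x, y, z))
    pd.DataFrame(
        recs, columns=["frame", "time_s", "keypoint", "x_mm", "y_mm", "z_mm"]
    ).to_csv(path, index=False)


def read_pose_csv(path) -> PoseTimeSeries:
    """Read a long-format pose CSV written by :func:`write_pose_csv`."""
    df = pd.read_csv(path)
    frames = np.sort(df["frame"].unique())
    keypoints = tuple(k for k in KEYPOINTS if k in set(df["keypoint"]))
    if not keypoints:
        keypoints = tuple(sorted(df["keypoint"].unique()))
    times = np.empty(len(frames))
    pos = np.empty((len(frames), len(keypoints), 3))
    kp_index = {k: j for j, k in enumerate(keypoints)}
    frame_index = {f: i for i, f in enumerate(frames)}
    for rec in df.itertuples(index=False):
        i = frame_index[rec.frame]
        j = kp_index[rec.keypoint]
        times[i] = rec.time_s
        pos[i, j] = (rec.x_mm, rec.y_mm, rec.z_mm)
    return PoseTimeSeries(times=times, positions=pos, keypoints=keypoints)
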