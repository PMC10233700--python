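"""Synthetic study generator.

Everything downstream of the scanner is testable without real data by
simulating the study at three levels:

1. **Design** — subjects, scans, maternal/placental/fetal covariates and
   the oxygen-epoch schedule, drawn with the cohort's category
   frequencies (default frequencies follow the observed cohort of 52
   singleton pregnancies / 76 scans).
2. **AMT tables** — per scan x epoch x joint movement times drawn from
   the log-linear generative model the statistics module fits:
   ``log AMT = baseline + fixed effects + interactions + u_subject +
   u_scan_in_position + eps``.  Planted effect presets mirror the fitted
   study contrasts, converted from percent to log scale via
   ``beta = ln(1 + pct/100)``.
3. **Trajectories and volumes** — bout-structured keypoint trajectories
   whose AMT matches a target (so the kinematics stage can be checked by
   round trip), and BOLD-like 4D phantoms with one Gaussian blob per
   keypoint on the 3 mm acquisition grid (so the tracking stage can be
   trained and evaluated end to end).

All randomness flows from one explicit top-level seed through named
``numpy`` substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .keypoints import KEYPOINTS, joint_descriptor
from .kinematics import PoseTimeSeries, V_TH_DEFAULT
from .tracking import VolumeGrid

__all__ = [
    "StudyDesign",
    "DesignConfig",
    "EffectSpec",
    "pct_to_log",
    "log_to_pct",
    "study_effect_spec",
    "null_effect_spec",
    "OXYGEN_PCT",
    "DISTAL_MIDDLE_PCT",
    "MIDDLE_PROXIMAL_PCT",
    "GA_EXTREMITY_PCT",
    "GA_SIDE_PCT",
    "generate_design",
    "generate_amt_table",
    "generate_trajectory",
    "generate_pose_series",
    "render_frame",
    "render_volumes",
    "simulate_tracking_scene",
    "ANATOMY_FRACTIONS",
]

# ---------------------------------------------------------------------------
# planted effect sizes (percent scale, as reported by the fitted study model)
# ---------------------------------------------------------------------------

#: Hyperoxia-vs-normoxia percent change in AMT.
OXYGEN_PCT = 20.7
#: Distal-vs-middle joint percent change.
DISTAL_MIDDLE_PCT = 20.6
#: Middle-vs-proximal joint percent change.
MIDDLE_PROXIMAL_PCT = 23.8
#: Lower-vs-upper extremity percent change per gestational-age week.
GA_EXTREMITY_PCT = {
    27: 94.4,
    28: -10.6,
    29: -39.3,
    30: -25.7,
    31: -10.7,
    32: 6.9,
    33: 15.8,
    34: 6.7,
    35: -5.0,
    36: 39.4,
    37: 12.3,
    38: -27.0,
}
#: Left-vs-right side percent change per gestational-age week.
GA_SIDE_PCT = {30: -34.4}


def pct_to_log(pct: float) -> float:
    """Percent effect -> log-scale coefficient: ``ln(1 + pct/100)``."""
    if pct <= -100:
        raise ValueError("percent effect must exceed -100")
    return math.log1p(pct / 100.0)


def log_to_pct(beta: float) -> float:
    """Log-scale coefficient -> percent effect: ``(exp(beta) - 1) * 100``."""
    return (math.exp(beta) - 1.0) * 100.0


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "maternal_position": ("left_lateral", "right_lateral", "supine", "tilt"),
    "parity": ("multipara", "primipara", "unknown"),
    "placental_position": ("anterior", "posterior", "previa", "superior"),
    "fetal_sex": ("female", "male"),
    "fetal_position": (
        "left_occiput",
        "left_sacrum",
        "occiput_anterior",
        "right_occiput",
        "right_sacrum",
    ),
    "oxygen": ("hyperoxia", "normoxia"),
    "distance_class": ("distal", "middle", "proximal"),
    "extremity": ("lower", "upper"),
    "side": ("left", "right"),
}


@dataclass(frozen=True)
class StudyDesign:
    """Covariates of one scan (one BOLD dataset of one subject)."""

    subject_id: str
    scan_id: str
    maternal_position: str
    parity: str
    placental_position: str
    fetal_sex: str
    fetal_position: str
    ga_weeks: float
    epoch_schedule: tuple[tuple[str, float], ...]  # (condition, duration s)

    def __post_init__(self) -> None:
        if not 24.0 <= self.ga_weeks <= 40.0:
            raise ValueError("ga_weeks outside [24, 40]")
        conds = [c for c, _ in self.epoch_schedule]
        if sorted(conds) != ["hyperoxia", "normoxia"]:
            raise ValueError("each scan needs exactly one normoxia and one hyperoxia epoch")
        for cond, dur in self.epoch_schedule:
            if not 300.0 <= dur <= 600.0:
                raise ValueError(f"{cond} epoch duration {dur} outside [300, 600] s")
        for factor in ("maternal_position", "parity", "placental_position",
                       "fetal_sex", "fetal_position"):
            if getattr(self, factor) not in FACTOR_LEVELS[factor]:
                raise ValueError(f"invalid {factor}: {getattr(self, factor)!r}")

    @property
    def ga_group(self) -> int:
        """Gestational age rounded to the nearest week."""
        return int(round(self.ga_weeks))

    def epoch_windows(self) -> tuple[tuple[str, float, float], ...]:
        """(condition, start_s, end_s), epochs laid out back to back."""
        out, t = [], 0.0
        for cond, dur in self.epoch_schedule:
            out.append((cond, t, t + dur))
            t += dur
        return tuple(out)


def _cohort(counts: Mapping[str, int]) -> dict[str, float]:
    tot = sum(counts.values())
    return {k: v / tot for k, v in counts.items()}


@dataclass
class DesignConfig:
    """Sampling frequencies and ranges for the design generator.

    Defaults follow the observed cohort (subject-level frequencies from
    the 52 singleton pregnancies; scan structure from the 76 scans).
    """

    maternal_position_freq: Mapping[str, float] = field(
        default_factory=lambda: _cohort(
            {"left_lateral": 52, "supine": 20, "right_lateral": 2, "tilt": 2}
        )
    )
    parity_freq: Mapping[str, float] = field(
        default_factory=lambda: _cohort({"primipara": 24, "multipara": 20, "unknown": 8})
    )
    placental_position_freq: Mapping[str, float] = field(
        default_factory=lambda: _cohort(
            {"anterior": 26, "posterior": 24, "previa": 1, "superior": 1}
        )
    )
    fetal_sex_freq: Mapping[str, float] = field(
        default_factory=lambda: _cohort({"male": 31, "female": 21})
    )
    fetal_position_freq: Mapping[str, float] = field(
        default_factory=lambda: _cohort(
            {
                "left_occiput": 25,
                "right_occiput": 15,
                "left_sacrum": 4,
                "right_sacrum": 5,
                "occiput_anterior": 3,
            }
        )
    )
    #: Probability that a subject is scanned in two maternal positions /
    #: twice in the same position (19/52 and 5/52 in the cohort).
    p_two_positions: float = 19 / 52
    p_two_scans_same_position: float = 5 / 52
    #: Gestational-age sampling: "uniform" on ga_range, or "empirical"
    #: (normal 32.08 +/- 2.71, clipped to ga_range).
    ga_distribution: str = "uniform"
    ga_range: tuple[float, float] = (24.0, 40.0)
    ga_mean: float = 32.08
    ga_sd: float = 2.71
    epoch_duration_range: tuple[float, float] = (300.0, 600.0)
    dt_range: tuple[float, float] = (2.5, 4.0)

    def validate(self) -> None:
        for name in (
            "maternal_position_freq",
            "parity_freq",
            "placental_position_freq",
            "fetal_sex_freq",
            "fetal_position_freq",
        ):
            freq = getattr(self, name)
            factor = name[: -len("_freq")]
            unknown = set(freq) - set(FACTOR_LEVELS[factor])
            if unknown:
                raise ValueError(f"{name}: unknown levels {sorted(unknown)}")
            if any(p < 0 for p in freq.values()):
                raise ValueError(f"{name}: negative probability")
            if abs(sum(freq.values()) - 1.0) > 1e-8:
                raise ValueError(f"{name} does not sum to 1")
        if not (24.0 <= self.ga_range[0] < self.ga_range[1] <= 40.0):
            raise ValueError("ga_range must be within [24, 40]")
        if self.ga_distribution not in ("uniform", "empirical"):
            raise ValueError("ga_distribution must be 'uniform' or 'empirical'")


def _draw(rng: np.random.Generator, freq: Mapping[str, float]) -> str:
    levels = sorted(freq)
    p = np.array([freq[l] for l in levels])
    return levels[rng.choice(len(levels), p=p / p.sum())]


def generate_design(
    n_subjects: int,
    seed: int = 0,
    config: DesignConfig | None = None,
) -> list[StudyDesign]:
    """Draw a reproducible study design: one record per scan.

    Subject-level covariates are shared by a subject's scans; the
    maternal position and epoch schedule are per scan.  Roughly a third
    of subjects get two scans (two positions, or a repeat in the same
    position), matching the cohort structure.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or DesignConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD]))

    designs: list[StudyDesign] = []
    for s in range(n_subjects):
        sid = f"S{s + 1:04d}"
        parity = _draw(rng, config.parity_freq)
        placenta = _draw(rng, config.placental_position_freq)
        sex = _draw(rng, config.fetal_sex_freq)
        fpos = _draw(rng, config.fetal_position_freq)
        lo, hi = config.ga_range
        if config.ga_distribution == "uniform":
            ga = float(rng.uniform(lo, hi))
        else:
            ga = float(np.clip(rng.normal(config.ga_mean, config.ga_sd), lo, hi))

        u = rng.random()
        pos1 = _draw(rng, config.maternal_position_freq)
        if u < config.p_two_positions:
            rest = {
                k: v for k, v in config.maternal_position_freq.items() if k != pos1
            }
            if sum(rest.values()) > 0:
                rest = {k: v / sum(rest.values()) for k, v in rest.items()}
                positions = [pos1, _draw(rng, rest)]
            else:
                positions = [pos1]
        elif u < config.p_two_positions + config.p_two_scans_same_position:
            positions = [pos1, pos1]
        else:
            positions = [pos1]

        for j, pos in enumerate(positions):
            d1, d2 = rng.uniform(*config.epoch_duration_range, size=2)
            designs.append(
                StudyDesign(
                    subject_id=sid,
                    scan_id=f"{sid}-{chr(ord('A') + j)}",
                    maternal_position=pos,
                    parity=parity,
                    placental_position=placenta,
                    fetal_sex=sex,
                    fetal_position=fpos,
                    ga_weeks=ga,
                    epoch_schedule=(("normoxia", float(d1)), ("hyperoxia", float(d2))),
                )
            )
    return designs


# ---------------------------------------------------------------------------
# AMT generative model
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """Planted parameters of the log-linear AMT model.

    ``fixed_effects`` maps factor -> level -> log-scale coefficient
    (levels omitted act as the zero reference).  ``interaction_effects``
    maps an interaction name ``"ga_group:extremity"`` or
    ``"ga_group:side"`` to ``{(week, level): coefficient}``.
    """

    baseline_log_amt: float = math.log(60.0)
    fixed_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    interaction_effects: dict[str, dict[tuple[int, str], float]] = field(
        default_factory=dict
    )
    sd_subject: float = 0.3
    sd_scan_within_position: float = 0.2
    sd_residual: float = 0.5

    def __post_init__(self) -> None:
        for sd in (self.sd_subject, self.sd_scan_within_position, self.sd_residual):
            if sd < 0:
                raise ValueError("random-effect SDs must be non-negative")
        for factor, levels in self.fixed_effects.items():
            if factor not in FACTOR_LEVELS and factor != "ga_group":
                raise ValueError(f"unknown factor in fixed_effects: {factor!r}")
            if factor in FACTOR_LEVELS:
                bad = set(levels) - set(FACTOR_LEVELS[factor])
                if bad:
                    raise ValueError(f"unknown levels for {factor}: {sorted(bad)}")
            for b in levels.values():
                if not np.isfinite(b):
                    raise ValueError("non-finite effect coefficient")
        for name, terms in self.interaction_effects.items():
            if name not in ("ga_group:extremity", "ga_group:side"):
                raise ValueError(f"unsupported interaction {name!r}")
            factor = name.split(":")[1]
            for (week, level), b in terms.items():
                if level not in FACTOR_LEVELS[factor]:
                    raise ValueError(f"unknown {factor} level {level!r}")
                if not np.isfinite(b):
                    raise ValueError("non-finite interaction coefficient")


def study_effect_spec(
    baseline_log_amt: float = math.log(60.0),
    sd_subject: float = 0.3,
    sd_scan_within_position: float = 0.2,
    sd_residual: float = 0.5,
) -> EffectSpec:
    """Effect preset planting the fitted study contrasts.

    Oxygen, the two joint-distance steps and the per-week
    GA x extremity / GA x side contrasts are converted from percent to
    log scale; all other factors are null.  The distal level is the sum
    of the two distance steps on the log scale, so the pairwise
    distal-middle and middle-proximal contrasts each match their percent
    value exactly.
    """
    middle = pct_to_log(MIDDLE_PROXIMAL_PCT)
    distal = middle + pct_to_log(DISTAL_MIDDLE_PCT)
    return EffectSpec(
        baseline_log_amt=baseline_log_amt,
        fixed_effects={
            "oxygen": {"hyperoxia": pct_to_log(OXYGEN_PCT)},
            "distance_class": {"middle": middle, "distal": distal},
        },
        interaction_effects={
            "ga_group:extremity": {
                (w, "lower"): pct_to_log(p) for w, p in GA_EXTREMITY_PCT.items()
            },
            "ga_group:side": {
                (w, "left"): pct_to_log(p) for w, p in GA_SIDE_PCT.items()
            },
        },
        sd_subject=sd_subject,
        sd_scan_within_position=sd_scan_within_position,
        sd_residual=sd_residual,
    )


def null_effect_spec(**kwargs) -> EffectSpec:
    """All fixed and interaction effects zero (for calibration runs)."""
    return EffectSpec(**kwargs)


def generate_amt_table(
    designs: Sequence[StudyDesign],
    effects: EffectSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an analysis table from the log-linear generative model.

    One row per scan x epoch x joint:
    ``AMT = exp(baseline + fixed + interactions + u_subject +
    u_scan_in_position + eps)`` with ``u`` and ``eps`` independent
    Gaussians.  The subject effect is shared by all rows of a subject;
    the scan-within-position effect by all rows of one
    (subject, maternal position) cell.
    """
    ss = np.random.SeedSequence([int(seed), 0xA])
    rng_u, rng_v, rng_e = (np.random.default_rng(s) for s in ss.spawn(3))

    subjects = sorted({d.subject_id for d in designs})
    u_subject = dict(zip(subjects, rng_u.normal(0.0, effects.sd_subject, len(subjects))))
    cells = sorted({(d.subject_id, d.maternal_position) for d in designs})
    u_cell = dict(
        zip(cells, rng_v.normal(0.0, effects.sd_scan_within_position, len(cells)))
    )

    ga_ext = effects.interaction_effects.get("ga_group:extremity", {})
    ga_side = effects.interaction_effects.get("ga_group:side", {})

    rows = []
    for d in designs:
        design_levels = {
            "maternal_position": d.maternal_position,
            "parity": d.parity,
            "placental_position": d.placental_position,
            "fetal_sex": d.fetal_sex,
            "fetal_position": d.fetal_position,
            "ga_group": str(d.ga_group),
        }
        base = effects.baseline_log_amt + u_subject[d.subject_id] + u_cell[
            (d.subject_id, d.maternal_position)
        ]
        for factor, levels in effects.fixed_effects.items():
            if factor in design_levels:
                base_add = levels.get(design_levels[factor], 0.0)
                base += base_add
        for cond, start, end in d.epoch_windows():
            oxy = effects.fixed_effects.get("oxygen", {}).get(cond, 0.0)
            for name in KEYPOINTS:
                jd = joint_descriptor(name)
                eta = base + oxy
                eta += effects.fixed_effects.get("distance_class", {}).get(
                    jd.distance_class, 0.0
                )
                eta += effects.fixed_effects.get("extremity", {}).get(jd.extremity, 0.0)
                eta += effects.fixed_effects.get("side", {}).get(jd.side, 0.0)
                eta += ga_ext.get((d.ga_group, jd.extremity), 0.0)
                eta += ga_side.get((d.ga_group, jd.side), 0.0)
                eta += rng_e.normal(0.0, effects.sd_residual)
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
                        "amt_s": float(np.exp(eta)),
                        "epoch_duration_s": end - start,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_trajectory(
    target_amt: float,
    total_duration: float,
    dt: float,
    amplitude: float = 15.0,
    seed: int = 0,
    keypoint: str = "left_wrist",
    mean_bout_intervals: float = 3.0,
    start_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> PoseTimeSeries:
    """Single-keypoint trajectory whose AMT round-trips to ``target_amt``.

    Movement is a bout process: alternating rest/move states with
    (geometric) dwell times, adjusted to hit exactly
    ``round(target_amt / dt)`` moving intervals.  Moving intervals step
    ``amplitude`` mm in a random direction (speed ``amplitude/dt`` must
    exceed the 3 mm/s threshold); resting intervals drift at 30% of the
    threshold speed, strictly below it.

    Frames cover ``[0, total_duration)`` at spacing ``dt``
    (``total_duration / dt`` frames), so the largest attainable AMT is
    ``total_duration - dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if amplitude / dt <= V_TH_DEFAULT:
        raise ValueError(
            f"amplitude/dt = {amplitude / dt:.2f} mm/s must exceed the "
            f"{V_TH_DEFAULT} mm/s threshold"
        )
    n_frames = int(round(total_duration / dt))
    n_int = n_frames - 1
    if n_int < 1:
        raise ValueError("total_duration shorter than one frame interval")
    k_move = int(round(target_amt / dt))
    if not 0 <= k_move <= n_int:
        raise ValueError(
            f"target AMT {target_amt} s infeasible: {n_int} intervals of {dt} s"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7]))
    frac = k_move / n_int
    moving = np.zeros(n_int, dtype=bool)
    if 0 < frac < 1:
        p_move = 1.0 / mean_bout_intervals
        mean_rest = mean_bout_intervals * (1 - frac) / frac
        p_rest = 1.0 / max(mean_rest, 1.0)
        state = rng.random() < frac
        for i in range(n_int):
            moving[i] = state
            if rng.random() < (p_move if state else p_rest):
                state = not state
        # correct the count to exactly k_move
        excess = int(moving.sum()) - k_move
        if excess > 0:
            on = rng.permutation(np.flatnonzero(moving))
            moving[on[:excess]] = False
        elif excess < 0:
            off = rng.permutation(np.flatnonzero(~moving))
            moving[off[:-excess]] = True
    elif frac == 1:
        moving[:] = True

    steps = np.where(
        moving[:, None],
        amplitude * _unit_vectors(rng, n_int),
        0.3 * V_TH_DEFAULT * dt * _unit_vectors(rng, n_int),
    )
    pos = np.vstack([np.asarray(start_mm, float), steps]).cumsum(axis=0)
    times = dt * np.arange(n_frames)
    return PoseTimeSeries(times=times, positions=pos[:, None, :], keypoints=(keypoint,))


def generate_pose_series(
    target_amt_per_keypoint: Mapping[str, Mapping[str, float]],
    schedule: Sequence[tuple[str, float, float]],
    dt: float,
    amplitude: float = 15.0,
    seed: int = 0,
    center_mm: Sequence[float] = (36.0, 36.0, 36.0),
) -> PoseTimeSeries:
    """Twelve-keypoint pose series for a whole scan.

    ``target_amt_per_keypoint[condition][keypoint]`` gives the AMT (s)
    to plant in each epoch.  Frames sit on one global ``dt`` lattice;
    the frames of each epoch are filled from an independent trajectory
    segment, so the planted AMT is recovered per epoch after
    :func:`~fetalkin.kinematics.split_by_epoch` (to within one ``dt``;
    the interval straddling an epoch boundary carries the jump between
    segments and is dropped there).  Each keypoint starts near its
    anatomical offset around ``center_mm``.
    """
    ss = np.random.SeedSequence([int(seed), 0x17])
    kid_seeds = ss.generate_state(len(KEYPOINTS) * len(schedule))
    total_end = max(end for _, _, end in schedule)
    times = dt * np.arange(int(np.floor(total_end / dt + 1e-9)) + 1)
    positions = np.zeros((len(times), len(KEYPOINTS), 3))
    filled = np.zeros(len(times), dtype=bool)
    s = 0
    last = len(schedule) - 1
    for j, (cond, start, end) in enumerate(schedule):
        if j == last:
            sel = (times >= start) & (times <= end)
        else:
            sel = (times >= start) & (times < end)
        n_frames = int(sel.sum())
        if n_frames < 2:
            s += len(KEYPOINTS)
            continue
        for k, name in enumerate(KEYPOINTS):
            target = float(target_amt_per_keypoint.get(cond, {}).get(name, 0.0))
            target = min(max(target, 0.0), (n_frames - 1) * dt)
            traj = generate_trajectory(
                target_amt=target,
                total_duration=n_frames * dt,
                dt=dt,
                amplitude=amplitude,
                seed=int(kid_seeds[s]) % (2**31),
                keypoint=name,
                start_mm=np.asarray(center_mm, float)
                + 20.0 * (np.array(ANATOMY_FRACTIONS[name]) - 0.5),
            )
            positions[sel, k, :] = traj.positions[:n_frames, 0, :]
            s += 1
        filled |= sel
    if not filled.all():  # frames outside every window: hold the last pose
        idx = np.flatnonzero(filled)
        for i in np.flatnonzero(~filled):
            src = idx[idx < i]
            positions[i] = positions[src[-1]] if len(src) else positions[idx[0]]
    return PoseTimeSeries(times=times, positions=positions, keypoints=KEYPOINTS)


# ---------------------------------------------------------------------------
# volume phantoms
# ---------------------------------------------------------------------------

#: Nominal keypoint positions as fractions of the grid extent — a
#: stylized, roughly fetal layout (shoulders superior, ankles inferior,
#: consistent left/right lateralization).
ANATOMY_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "left_shoulder": (0.38, 0.45, 0.74),
    "right_shoulder": (0.62, 0.45, 0.74),
    "left_elbow": (0.29, 0.58, 0.60),
    "right_elbow": (0.71, 0.58, 0.60),
    "left_wrist": (0.24, 0.71, 0.47),
    "right_wrist": (0.76, 0.71, 0.47),
    "left_hip": (0.40, 0.42, 0.38),
    "right_hip": (0.60, 0.42, 0.38),
    "left_knee": (0.31, 0.58, 0.26),
    "right_knee": (0.69, 0.58, 0.26),
    "left_ankle": (0.26, 0.72, 0.14),
    "right_ankle": (0.74, 0.72, 0.14),
}


def simulate_tracking_scene(
    n_frames: int,
    grid: VolumeGrid | None = None,
    jitter_sd_mm: float = 4.0,
    dt: float = 3.0,
    seed: int = 0,
) -> PoseTimeSeries:
    """Pose series with keypoints jittering around anatomical positions.

    Used to create labelled phantoms for tracker training: keypoints
    stay in distinct spatial zones (as real joints do for a roughly
    stable fetal lie) while moving frame to frame.
    """
    grid = grid or VolumeGrid(shape=(24, 24, 24))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C]))
    extent = np.array(grid.spacing) * (np.array(grid.shape) - 1)
    origin = np.array(grid.origin)
    margin = 1.5 * np.array(grid.spacing)
    pos = np.empty((n_frames, len(KEYPOINTS), 3))
    for k, name in enumerate(KEYPOINTS):
        nominal = origin + np.array(ANATOMY_FRACTIONS[name]) * extent
        jitter = rng.normal(0.0, jitter_sd_mm, size=(n_frames, 3))
        pos[:, k, :] = np.clip(
            nominal + jitter, origin + margin, origin + extent - margin
        )
    times = dt * np.arange(n_frames)
    return PoseTimeSeries(times=times, positions=pos, keypoints=KEYPOINTS)


def render_frame(
    positions_mm: np.ndarray,
    grid: VolumeGrid,
    blob_sigma: float = 6.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """One BOLD-like volume: Gaussian noise plus one blob per keypoint."""
    positions_mm = np.atleast_2d(np.asarray(positions_mm, float))
    inside = grid.contains(positions_mm)
    if not inside.all():
        raise ValueError("keypoint outside grid extent")
    rng = np.random.default_rng(seed)
    vol = (
        rng.normal(0.0, noise_sd, size=grid.shape)
        if noise_sd > 0
        else np.zeros(grid.shape)
    )
    ax, ay, az = grid.axes_mm()
    s2 = 2.0 * blob_sigma**2
    for t in positions_mm:
        gx = np.exp(-((ax - t[0]) ** 2) / s2)
        gy = np.exp(-((ay - t[1]) ** 2) / s2)
        gz = np.exp(-((az - t[2]) ** 2) / s2)
        vol += np.einsum("i,j,k->ijk", gx, gy, gz)
    return vol


def render_volumes(
    pose: PoseTimeSeries,
    grid: VolumeGrid | None = None,
    blob_sigma: float = 6.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a pose series as a 4D phantom volume series.

    Returns the ``(n_frames, nx, ny, nz)`` array and a ground-truth
    table with both voxel and mm coordinates per (frame, keypoint).
    Per-frame noise seeds are spawned from ``seed``.
    """
    grid = grid or VolumeGrid(shape=(24, 24, 24))
    frame_seeds = np.random.SeedSequence([int(seed), 0x4D]).generate_state(
        pose.n_frames
    )
    vols = np.empty((pose.n_frames, *grid.shape))
    truth_rows = []
    for i in range(pose.n_frames):
        vols[i] = render_frame(
            pose.positions[i], grid, blob_sigma, noise_sd, seed=int(frame_seeds[i])
        )
        vox = grid.mm_to_voxel(pose.positions[i])
        for k, name in enumerate(pose.keypoints):
            truth_rows.append(
                {
                    "frame": i,
                    "keypoint": name,
                    "x_mm": pose.positions[i, k, 0],
                    "y_mm": pose.positions[i, k, 1],
                    "z_mm": pose.positions[i, k, 2],
                    "vx": vox[k, 0],
                    "vy": vox[k, 1],
                    "vz": vox[k, 2],
                }
            )
    return vols, pd.DataFrame(truth_rows)
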