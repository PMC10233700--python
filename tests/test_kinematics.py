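"""Velocity and absolute-movement-time computations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalkin.keypoints import KEYPOINTS, joint_descriptor
from fetalkin.kinematics import (
    PoseTimeSeries,
    VelocitySeries,
    build_amt_table,
    compute_amt,
    compute_velocity,
    read_pose_csv,
    split_by_epoch,
    write_pose_csv,
)
from fetalkin.synthetic import StudyDesign, generate_trajectory


def single_kp_series(steps_mm, dt):
    """Pose series for one keypoint from a list of per-interval steps."""
    pos = np.vstack([[0.0, 0.0, 0.0], np.asarray(steps_mm, float)]).cumsum(axis=0)
    return PoseTimeSeries(
        times=dt * np.arange(len(pos)), positions=pos[:, None, :], keypoints=("left_wrist",)
    )


def brute_force_amt(positions, dt, v_th):
    """Independent oracle: explicit loop over inter-frame intervals."""
    n_moving = 0
    for i in range(len(positions) - 1):
        v = np.sqrt(np.sum((positions[i + 1] - positions[i]) ** 2)) / dt
        if v > v_th:
            n_moving += 1
    return dt * n_moving


class TestVelocity:
    def test_constant_position_gives_zero_speed(self):
        vel = compute_velocity(single_kp_series([[0, 0, 0]] * 5, dt=3.0))
        assert np.all(vel.speeds == 0.0)

    @pytest.mark.parametrize(
        "step, dt, expected",
        [((3, 0, 0), 3.0, 1.0), ((6, 8, 0), 2.5, 4.0)],
    )
    def test_speed_is_displacement_norm_over_dt(self, step, dt, expected):
        vel = compute_velocity(single_kp_series([step] * 4, dt=dt))
        assert vel.speeds == pytest.approx(expected)

    def test_two_frames_minimum(self):
        with pytest.raises(ValueError):
            compute_velocity(
                PoseTimeSeries(times=[0.0], positions=np.zeros((1, 1, 3)),
                               keypoints=("left_wrist",))
            )

    def test_nonuniform_timestamps_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            PoseTimeSeries(
                times=[0.0, 3.0, 7.0],
                positions=np.zeros((3, 1, 3)),
                keypoints=("left_wrist",),
            )


class TestAMT:
    def test_no_movement_gives_zero(self):
        vel = VelocitySeries(speeds=np.zeros((10, 1)), dt=3.0, keypoints=("left_wrist",))
        assert compute_amt(vel) == pytest.approx(0.0)

    def test_threshold_inequality_is_strict(self):
        vel = VelocitySeries(
            speeds=np.full((8, 1), 3.0), dt=3.0, keypoints=("left_wrist",)
        )
        assert compute_amt(vel, v_th=3.0) == pytest.approx(0.0)

    def test_counts_exceedances_times_dt(self):
        vel = VelocitySeries(
            speeds=np.array([4, 2, 5, 3.1])[:, None], dt=3.0, keypoints=("left_wrist",)
        )
        assert compute_amt(vel, v_th=3.0) == pytest.approx(9.0)

    def test_negative_threshold_rejected(self):
        vel = VelocitySeries(speeds=np.zeros((3, 1)), dt=3.0, keypoints=("left_wrist",))
        with pytest.raises(ValueError):
            compute_amt(vel, v_th=-1.0)

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 40))
            dt = float(rng.uniform(2.5, 4.0))
            pos = rng.normal(scale=8.0, size=(n, 3)).cumsum(axis=0)
            pose = PoseTimeSeries(
                times=dt * np.arange(n), positions=pos[:, None, :],
                keypoints=("left_wrist",),
            )
            v_th = float(rng.uniform(0, 6))
            vel = compute_velocity(pose)
            # compare at the effective dt the velocity stage derives
            assert compute_amt(vel, v_th)[0] == brute_force_amt(pos, vel.dt, v_th)

    @given(
        st.lists(st.floats(0, 20), min_size=2, max_size=50),
        st.floats(0, 10),
        st.floats(0, 10),
    )
    @settings(deadline=None, max_examples=60)
    def test_monotone_nonincreasing_in_threshold(self, speeds, th1, th2):
        vel = VelocitySeries(
            speeds=np.asarray(speeds)[:, None], dt=3.0, keypoints=("left_wrist",)
        )
        lo, hi = sorted([th1, th2])
        assert compute_amt(vel, hi) <= compute_amt(vel, lo)

    def test_invariant_to_rigid_translation_and_axis_relabeling(self, rng):
        pos = rng.normal(scale=8.0, size=(30, 3)).cumsum(axis=0)
        base = single_kp_series(np.diff(pos, axis=0), dt=3.0)
        amt = compute_amt(compute_velocity(base))
        shifted = PoseTimeSeries(
            times=base.times, positions=base.positions + [100.0, -50.0, 7.0],
            keypoints=base.keypoints,
        )
        permuted = PoseTimeSeries(
            times=base.times, positions=base.positions[:, :, [2, 0, 1]],
            keypoints=base.keypoints,
        )
        assert compute_amt(compute_velocity(shifted)) == pytest.approx(amt)
        assert compute_amt(compute_velocity(permuted)) == pytest.approx(amt)

    def test_concatenation_within_one_dt(self, rng):
        dt = 3.0
        a = rng.normal(scale=8.0, size=(20, 3)).cumsum(axis=0)
        b = rng.normal(scale=8.0, size=(15, 3)).cumsum(axis=0) + a[-1]
        whole = np.vstack([a, b])
        pose = single_kp_series(np.diff(whole, axis=0), dt)
        pa = single_kp_series(np.diff(a, axis=0), dt)
        pb = single_kp_series(np.diff(b, axis=0), dt)
        total = compute_amt(compute_velocity(pose))[0]
        parts = compute_amt(compute_velocity(pa))[0] + compute_amt(compute_velocity(pb))[0]
        assert abs(total - parts) <= dt + 1e-9


class TestSplitByEpoch:
    def test_single_epoch_is_identity(self, rng):
        pose = single_kp_series(rng.normal(size=(10, 3)), dt=3.0)
        out = split_by_epoch(pose, [("normoxia", 0.0, 100.0)])
        assert list(out) == ["normoxia"]
        np.testing.assert_array_equal(out["normoxia"].positions, pose.positions)

    def test_boundary_between_frames_drops_straddling_interval(self, rng):
        dt = 3.0
        pose = single_kp_series(rng.normal(size=(9, 3)), dt=dt)  # frames at 0..27 s
        out = split_by_epoch(
            pose, [("normoxia", 0.0, 13.5), ("hyperoxia", 13.5, 27.0)]
        )
        assert out["normoxia"].n_frames + out["hyperoxia"].n_frames == pose.n_frames
        assert out["normoxia"].times[-1] == 12.0
        assert out["hyperoxia"].times[0] == 15.0

    def test_epoch_amts_sum_to_total_within_one_dt(self, rng):
        dt = 3.0
        pose = single_kp_series(rng.normal(scale=8.0, size=(199, 3)), dt=dt)
        mid = pose.times[len(pose.times) // 2] + dt / 2
        out = split_by_epoch(
            pose, [("normoxia", 0.0, mid), ("hyperoxia", mid, pose.times[-1])]
        )
        total = compute_amt(compute_velocity(pose))[0]
        parts = sum(compute_amt(compute_velocity(p))[0] for p in out.values())
        assert abs(total - parts) <= dt + 1e-9

    def test_overlapping_epochs_rejected(self, rng):
        pose = single_kp_series(rng.normal(size=(5, 3)), dt=3.0)
        with pytest.raises(ValueError):
            split_by_epoch(pose, [("normoxia", 0.0, 10.0), ("hyperoxia", 5.0, 15.0)])


def _design(i, position="left_lateral"):
    return StudyDesign(
        subject_id=f"S{i:03d}",
        scan_id=f"S{i:03d}-A",
        maternal_position=position,
        parity="primipara",
        placental_position="anterior",
        fetal_sex="male",
        fetal_position="left_occiput",
        ga_weeks=30.0,
        epoch_schedule=(("normoxia", 300.0), ("hyperoxia", 300.0)),
    )


def _pose_for(design, rng, dt=3.0):
    n = int(600 / dt) + 1
    pos = rng.normal(scale=8.0, size=(n, 12, 3)).cumsum(axis=0)
    return PoseTimeSeries(times=dt * np.arange(n), positions=pos)


class TestBuildAmtTable:
    def test_full_study_row_count(self, rng):
        # 76 scans x 2 epochs x 12 joints
        designs = [_design(i) for i in range(76)]
        poses = {d.scan_id: (_pose_for(d, rng), d.epoch_windows()) for d in designs}
        table = build_amt_table(poses, designs)
        assert len(table) == 1824

    def test_position_sensitivity_subset_row_count(self, rng):
        # dropping the 4 tilt/right-lateral scans leaves 72 x 24 = 1728 rows
        designs = [_design(i) for i in range(72)]
        designs += [_design(100, "tilt"), _design(101, "right_lateral"),
                    _design(102, "right_lateral"), _design(103, "tilt")]
        keep = [d for d in designs if d.maternal_position in ("left_lateral", "supine")]
        poses = {d.scan_id: (_pose_for(d, rng), d.epoch_windows()) for d in keep}
        table = build_amt_table(poses, keep)
        assert len(table) == 1728

    def test_single_scan_single_epoch_gives_12_rows(self, rng):
        d = _design(0)
        pose = _pose_for(d, rng)
        table = build_amt_table(
            {d.scan_id: (pose, (("normoxia", 0.0, 600.0),))}, [d]
        )
        assert len(table) == 12
        assert set(table.keypoint) == set(KEYPOINTS)

    def test_joint_descriptors_populated(self, rng):
        d = _design(0)
        table = build_amt_table(
            {d.scan_id: (_pose_for(d, rng), d.epoch_windows())}, [d]
        )
        row = table[table.keypoint == "left_wrist"].iloc[0]
        jd = joint_descriptor("left_wrist")
        assert (row.distance_class, row.extremity, row.side) == (
            jd.distance_class, jd.extremity, jd.side,
        )
        assert table.amt_s.between(0, table.n_intervals * table.dt_s).all()
        # AMT is an integer multiple of dt
        ratio = table.amt_s / table.dt_s
        assert np.allclose(ratio, ratio.round())

    def test_scan_design_mismatch_rejected(self, rng):
        d = _design(0)
        poses = {d.scan_id: (_pose_for(d, rng), d.epoch_windows())}
        with pytest.raises(KeyError):
            build_amt_table(poses, [])
        with pytest.raises(KeyError):
            build_amt_table({}, [d])


def test_pose_csv_round_trip(tmp_path, rng):
    traj = generate_trajectory(30.0, 300.0, 3.0, seed=5)
    path = tmp_path / "pose.csv"
    write_pose_csv(path, traj)
    back = read_pose_csv(path)
    np.testing.assert_allclose(back.positions, traj.positions)
    np.testing.assert_allclose(back.times, traj.times)
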