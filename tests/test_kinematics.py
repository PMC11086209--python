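"""Marker pose rebasing and hand-movement metrics."""

import numpy as np
import pandas as pd
import pytest

from surgstress.errors import (
    InsufficientDataError,
    MissingStreamError,
    UndefinedRatioError,
)
from surgstress.kinematics import (
    MARKER_COLUMNS,
    MarkerObservation,
    RigidTransform,
    Trajectory,
    bimanuality_ratios,
    build_trajectory,
    kinematic_summary,
    rebase,
    substitute_depth,
    to_homogeneous,
)


def quaternion_rotation_matrix(rvec):
    """Independent oracle: rotation matrix via the unit quaternion map."""
    theta = np.linalg.norm(rvec)
    if theta == 0:
        return np.eye(3)
    axis = np.asarray(rvec) / theta
    w = np.cos(theta / 2.0)
    x, y, z = np.sin(theta / 2.0) * axis
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_transform(rng):
    rvec = rng.uniform(-1, 1, 3)
    rvec *= rng.uniform(0, np.pi) / np.linalg.norm(rvec)
    return to_homogeneous(rvec, rng.uniform(-1, 1, 3))


def obs_row(t, marker_id, transform, depth=None):
    from scipy.spatial.transform import Rotation

    rvec = Rotation.from_matrix(transform.R).as_rotvec()
    return {
        "t_unix": t,
        "marker_id": marker_id,
        "rx": rvec[0],
        "ry": rvec[1],
        "rz": rvec[2],
        "tx": transform.p[0],
        "ty": transform.p[1],
        "tz": transform.p[2],
        "depth_m": np.nan if depth is None else depth,
    }


class TestDepthSubstitution:
    def test_replaces_z_with_depth(self):
        obs = MarkerObservation(0.0, 2, [0, 0, 0], [0.1, 0.2, 0.50], depth_m=0.48)
        assert substitute_depth(obs).tvec.tolist() == [0.1, 0.2, 0.48]

    def test_no_depth_is_identity(self):
        obs = MarkerObservation(0.0, 2, [0, 0, 0], [0.1, 0.2, 0.5])
        assert substitute_depth(obs) is obs

    def test_depth_equal_to_z_is_fixed_point(self):
        obs = MarkerObservation(0.0, 2, [0, 0, 0], [0.1, 0.2, 0.5], depth_m=0.5)
        assert substitute_depth(obs).tvec.tolist() == [0.1, 0.2, 0.5]


class TestRodrigues:
    def test_zero_rvec_is_identity(self):
        assert np.allclose(to_homogeneous([0, 0, 0], [1, 2, 3]).R, np.eye(3))

    def test_quarter_turn_about_z(self):
        h = to_homogeneous([0, 0, np.pi / 2], [0, 0, 0])
        assert np.allclose(h.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_axis_angle_roundtrip(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(20):
            rvec = rng.uniform(-1, 1, 3)
            rvec *= rng.uniform(0.01, np.pi - 0.01) / np.linalg.norm(rvec)
            h = to_homogeneous(rvec, np.zeros(3))
            assert np.allclose(Rotation.from_matrix(h.R).as_rotvec(), rvec, atol=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(200):
            rvec = rng.uniform(-np.pi, np.pi, 3)
            got = to_homogeneous(rvec, np.zeros(3)).R
            assert np.max(np.abs(got - quaternion_rotation_matrix(rvec))) < 1e-9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            to_homogeneous([np.nan, 0, 0], [0, 0, 0])


class TestRebase:
    def test_same_pose_gives_identity(self, rng):
        h = random_transform(rng)
        res = rebase(h, h)
        assert np.allclose(res.R, np.eye(3), atol=1e-12)
        assert np.allclose(res.p, 0, atol=1e-12)

    def test_identity_reference_returns_pose(self, rng):
        h = random_transform(rng)
        res = rebase(RigidTransform.identity(), h)
        assert np.allclose(res.R, h.R) and np.allclose(res.p, h.p)

    def test_composition_inverse(self, rng):
        for _ in range(50):
            h_ref, h_k = random_transform(rng), random_transform(rng)
            res = rebase(h_ref, h_k)
            recomposed = h_ref @ res
            assert np.allclose(recomposed.R, h_k.R, atol=1e-9)
            assert np.allclose(recomposed.p, h_k.p, atol=1e-9)


class TestBuildTrajectory:
    def make_obs(self, rng, n=20, static_offset=(0.1, 0.2, 0.05)):
        """Hand marker rigidly attached relative to reference; camera wobbles."""
        rows = []
        offset = RigidTransform(np.eye(3), np.asarray(static_offset))
        ref_world = random_transform(rng)
        hand_world = ref_world @ offset
        for i in range(n):
            cam = random_transform(rng)  # fresh camera pose per frame
            cam_inv = cam.inverse()
            rows.append(obs_row(i * 0.1, 1, cam_inv @ ref_world))
            rows.append(obs_row(i * 0.1, 2, cam_inv @ hand_world))
        return pd.DataFrame(rows, columns=MARKER_COLUMNS)

    def test_camera_wobble_cancels(self, rng):
        traj = build_trajectory(self.make_obs(rng), "left")
        assert len(traj) == 20 and traj.n_dropped == 0
        assert np.allclose(traj.pos, [0.1, 0.2, 0.05], atol=1e-9)

    def test_frame_independence_under_global_motion(self, rng):
        df = self.make_obs(rng)
        traj = build_trajectory(df, "left")
        # rigidly move the whole scene (equivalently, the camera): premultiply
        g = random_transform(rng)
        moved = []
        for _, row in df.iterrows():
            h = to_homogeneous(row[["rx", "ry", "rz"]].to_numpy(),
                               row[["tx", "ty", "tz"]].to_numpy())
            moved.append(obs_row(row["t_unix"], int(row["marker_id"]), g @ h))
        traj2 = build_trajectory(pd.DataFrame(moved, columns=MARKER_COLUMNS), "left")
        assert np.max(np.abs(traj.pos - traj2.pos)) < 1e-9

    def test_missing_reference_errors(self):
        df = pd.DataFrame([obs_row(0.0, 2, RigidTransform.identity())],
                          columns=MARKER_COLUMNS)
        with pytest.raises(MissingStreamError):
            build_trajectory(df, "left")

    def test_all_hand_frames_missing(self, rng):
        df = self.make_obs(rng)
        df = df[df["marker_id"] == 1]
        traj = build_trajectory(df, "left")
        assert len(traj) == 0 and traj.n_dropped == 20

    def test_single_frame(self, rng):
        df = self.make_obs(rng, n=1)
        assert len(build_trajectory(df, "left")) == 1

    def test_depth_substitution_applied(self):
        ref = obs_row(0.0, 1, RigidTransform.identity())
        hand = obs_row(0.0, 2, RigidTransform(np.eye(3), np.array([0.1, 0.2, 0.5])),
                       depth=0.42)
        df = pd.DataFrame([ref, hand], columns=MARKER_COLUMNS)
        traj = build_trajectory(df, "left")
        assert traj.pos[0].tolist() == [0.1, 0.2, 0.42]


def line_trajectory(n=11, step=0.1, hz=10.0):
    t = np.arange(n) / hz
    pos = np.column_stack([np.arange(n) * step, np.zeros(n), np.zeros(n)])
    return Trajectory(t, pos, hand="right")


class TestKinematicSummary:
    def test_stationary_gives_zero_metrics(self):
        traj = Trajectory(np.arange(10) / 10.0, np.tile([0.3, -0.1, 0.2], (10, 1)),
                          hand="left")
        ks = kinematic_summary(traj)
        for v in (ks.std3d_m, ks.range_m, ks.total_dist_m, ks.avg_speed_mps,
                  ks.jerk_mps3):
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_straight_line_closed_form(self):
        ks = kinematic_summary(line_trajectory())
        assert ks.total_dist_m == pytest.approx(1.0)
        assert ks.avg_speed_mps == pytest.approx(1.0)
        assert ks.jerk_mps3 == pytest.approx(0.0, abs=1e-9)

    def test_unit_cube_range_is_sqrt3(self):
        corners = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
             [0, 1, 1], [1, 1, 1], [1, 0, 1], [0, 0, 1]], dtype=float
        )
        ks = kinematic_summary(Trajectory(np.arange(8) / 10.0, corners, hand="left"))
        assert ks.range_m == pytest.approx(np.sqrt(3.0))
        assert ks.extent_m == (1.0, 1.0, 1.0)

    def test_metric_scaling(self, rng):
        t = np.arange(50) / 10.0
        pos = rng.normal(0, 0.1, (50, 3)).cumsum(axis=0)
        a = kinematic_summary(Trajectory(t, pos, hand="left"))
        b = kinematic_summary(Trajectory(t, pos * 3.0, hand="left"))
        for attr in ("std3d_m", "range_m", "total_dist_m", "avg_speed_mps",
                     "jerk_mps3"):
            assert getattr(b, attr) == pytest.approx(3.0 * getattr(a, attr))

    def test_time_reversal_invariance(self, rng):
        t = np.arange(40) / 10.0
        pos = rng.normal(0, 0.05, (40, 3)).cumsum(axis=0)
        a = kinematic_summary(Trajectory(t, pos, hand="left"))
        b = kinematic_summary(Trajectory(t, pos[::-1], hand="left"))
        assert a.total_dist_m == pytest.approx(b.total_dist_m)
        assert a.std3d_m == pytest.approx(b.std3d_m)
        assert a.range_m == pytest.approx(b.range_m)

    def test_gap_not_interpolated_for_jerk(self):
        # wiggly segment, 1 s hole, wiggly segment: jerk computed per segment
        t = np.concatenate([np.arange(20) / 10.0, 3.0 + np.arange(20) / 10.0])
        rng = np.random.default_rng(7)
        pos = rng.normal(0, 0.01, (40, 3))
        ks = kinematic_summary(Trajectory(t, pos, hand="left"))
        assert ks.jerk_mps3 > 0

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError, match="jerk"):
            kinematic_summary(line_trajectory(n=3))
        with pytest.raises(InsufficientDataError):
            kinematic_summary(line_trajectory(n=1))


class TestBimanuality:
    def test_identical_summaries(self):
        ks = kinematic_summary(line_trajectory())
        assert bimanuality_ratios(ks, ks) == (1.0, 1.0)

    def test_dominant_ratio(self):
        left = kinematic_summary(line_trajectory())
        right = kinematic_summary(line_trajectory(step=0.17))
        dist_rate, _ = bimanuality_ratios(right, left)
        assert dist_rate == pytest.approx(1.7)

    def test_zero_left_metric_errors(self):
        left = kinematic_summary(
            Trajectory(np.arange(10) / 10.0, np.zeros((10, 3)), hand="left")
        )
        right = kinematic_summary(line_trajectory())
        with pytest.raises(UndefinedRatioError):
            bimanuality_ratios(right, left)
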