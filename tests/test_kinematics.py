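"""Forward kinematics, inverse kinematics, differentiation, comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exogait.kinematics import (CoordinateTrajectory, KinematicsError,
                                MarkerTrajectorySet, compare_human_robot_angles,
                                compare_ik_encoder, differentiate_trajectory,
                                forward_kinematics, marker_jacobian, solve_ik,
                                solve_ik_frame)
from exogait.model import (GROUND, InertialSegment, JointSpec, MarkerAttachment,
                           MultibodyModel)


def two_link_planar(L=0.5):
    """Two links along +X, pin joints about +Z, end marker at the tip."""
    segs = [
        InertialSegment("l1", 1.0, [L / 2, 0, 0], np.eye(3) * 0.01),
        InertialSegment("l2", 1.0, [L / 2, 0, 0], np.eye(3) * 0.01,
                        attached_markers=[
                            MarkerAttachment("tip", "l2", [L, 0, 0])]),
    ]
    joints = [
        JointSpec("j1", "pin", GROUND, "l1", axes=[[0, 0, 1]]),
        JointSpec("j2", "pin", "l1", "l2", parent_offset=[L, 0, 0],
                  axes=[[0, 0, 1]]),
    ]
    return MultibodyModel(segs, joints)


class TestForwardKinematics:
    def test_straight_chain(self):
        m = two_link_planar()
        fk = forward_kinematics(m, np.zeros(2))
        np.testing.assert_allclose(fk.markers[0], [1.0, 0, 0], atol=1e-12)

    def test_rotated_chain(self):
        m = two_link_planar()
        fk = forward_kinematics(m, [math.pi / 2, 0.0])
        np.testing.assert_allclose(fk.markers[0], [0, 1.0, 0], atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(KinematicsError, match="dimension"):
            forward_kinematics(two_link_planar(), np.zeros(3))

    def test_matches_brute_force_pose_composition(self):
        """Independent oracle: multiply the homogeneous transforms by hand."""
        m = two_link_planar()
        rng = np.random.default_rng(0)
        for _ in range(10):
            q = rng.uniform(-math.pi, math.pi, 2)

            def rotz(a):
                c, s = math.cos(a), math.sin(a)
                return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

            R1 = rotz(q[0])
            p2 = R1 @ [0.5, 0, 0]
            R2 = R1 @ rotz(q[1])
            tip = p2 + R2 @ [0.5, 0, 0]
            fk = forward_kinematics(m, q)
            np.testing.assert_allclose(fk.markers[0], tip, atol=1e-12)

    def test_jacobian_matches_finite_differences(self, human):
        rng = np.random.default_rng(1)
        q = rng.normal(0, 0.2, human.n_coordinates)
        fk = forward_kinematics(human, q)
        J = marker_jacobian(human, fk)
        h = 1e-7
        for ci in rng.choice(human.n_coordinates, size=8, replace=False):
            dq = np.zeros_like(q)
            dq[ci] = h
            dP = (forward_kinematics(human, q + dq).markers
                  - forward_kinematics(human, q - dq).markers) / (2 * h)
            np.testing.assert_allclose(J[:, :, ci], dP, atol=1e-6)


class TestInverseKinematics:
    def test_exact_recovery_noiseless(self, human):
        rng = np.random.default_rng(2)
        q_true = rng.normal(0, 0.15, human.n_coordinates)
        q_true[2] = 0.95
        fk = forward_kinematics(human, q_true)
        q0 = np.zeros(human.n_coordinates)
        q0[2] = 0.95
        res = solve_ik_frame(human, fk.markers,
                             np.ones(human.n_markers, bool), q0)
        assert res.converged
        assert np.abs(res.q - q_true).max() < 1e-6
        assert res.rms < 1e-8

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fk_ik_round_trip_property(self, human, seed):
        """IK on noiseless FK markers recovers any reachable pose."""
        rng = np.random.default_rng(seed)
        q_true = rng.uniform(-0.25, 0.25, human.n_coordinates)
        q_true[:3] += [0.1, 0.0, 0.95]
        fk = forward_kinematics(human, q_true)
        q0 = np.zeros(human.n_coordinates)
        q0[:3] = q_true[:3]
        res = solve_ik_frame(human, fk.markers,
                             np.ones(human.n_markers, bool), q0)
        assert np.abs(res.q - q_true).max() < 1e-6

    def test_objective_not_increased_from_start(self, human):
        rng = np.random.default_rng(3)
        q_true = rng.normal(0, 0.1, human.n_coordinates)
        q_true[2] = 0.95
        obs = forward_kinematics(human, q_true).markers + \
            rng.normal(0, 0.01, (human.n_markers, 3))
        q0 = np.zeros(human.n_coordinates)
        q0[2] = 0.95
        rms0 = float(np.sqrt(np.mean(np.sum(
            (obs - forward_kinematics(human, q0).markers) ** 2, axis=1))))
        res = solve_ik_frame(human, obs, np.ones(human.n_markers, bool), q0)
        assert res.rms <= rms0

    def test_occluded_segment_flagged_unobservable(self, human):
        q = np.zeros(human.n_coordinates)
        q[2] = 0.95
        fk = forward_kinematics(human, q)
        visible = np.ones(human.n_markers, bool)
        hand_idx = human.segment_index["hand_l"]
        visible[human.marker_segment == hand_idx] = False
        res = solve_ik_frame(human, fk.markers, visible, q)
        wrist = [human.coordinate_index["wrist_flexion_l"],
                 human.coordinate_index["wrist_deviation_l"]]
        assert set(wrist) <= set(res.unobservable)

    def test_rms_invariant_under_rigid_transform(self, human):
        """Moving observations and base pose together leaves the fit alone."""
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(4)
        q = rng.normal(0, 0.1, human.n_coordinates)
        q[2] = 0.95
        obs = forward_kinematics(human, q).markers + \
            rng.normal(0, 0.005, (human.n_markers, 3))
        vis = np.ones(human.n_markers, bool)
        r1 = solve_ik_frame(human, obs, vis, q)
        R = Rotation.from_euler("XYZ", [0.2, -0.1, 0.4]).as_matrix()
        t = np.array([0.5, -0.3, 0.1])
        obs2 = obs @ R.T + t
        q2 = q.copy()
        q2[:3] = R @ q[:3] + t
        q2[3:6] = Rotation.from_matrix(
            R @ Rotation.from_euler("XYZ", q[3:6]).as_matrix()).as_euler("XYZ")
        r2 = solve_ik_frame(human, obs2, vis, q2)
        assert r2.rms == pytest.approx(r1.rms, abs=1e-9)

    def test_trajectory_ik_passes_tolerance(self, human):
        rng = np.random.default_rng(5)
        T = 10
        q = np.zeros((T, human.n_coordinates))
        q[:, 2] = 0.95
        q[:, human.coordinate_index["knee_flexion_l"]] = \
            np.linspace(0, 0.8, T)
        frames = [forward_kinematics(human, qk).markers for qk in q]
        markers = {name: np.array([f[m] for f in frames])
                   for m, name in enumerate(human.marker_names)}
        res = solve_ik(human, MarkerTrajectorySet(
            time=np.arange(T) / 100.0, markers=markers))
        assert res.passed
        assert res.mean_rms < 1e-6
        np.testing.assert_allclose(res.trajectory.q, q, atol=1e-6)

    def test_large_marker_bias_fails_tolerance(self, human):
        rng = np.random.default_rng(6)
        q = np.zeros((3, human.n_coordinates))
        q[:, 2] = 0.95
        frames = [forward_kinematics(human, qk).markers for qk in q]
        markers = {}
        for m, name in enumerate(human.marker_names):
            bias = rng.normal(0, 1, 3)
            bias = 0.05 * bias / np.linalg.norm(bias)
            markers[name] = np.array([f[m] + bias for f in frames])
        res = solve_ik(human, MarkerTrajectorySet(
            time=np.arange(3) / 100.0, markers=markers))
        assert not res.passed

    def test_empty_trajectory_rejected(self, human):
        with pytest.raises(KinematicsError, match="empty"):
            solve_ik(human, MarkerTrajectorySet(time=np.zeros(0), markers={}))


class TestDifferentiation:
    def test_quadratic_acceleration(self):
        t = np.arange(0, 1, 0.01)
        traj = CoordinateTrajectory(time=t, q=(t ** 2)[:, None])
        out = differentiate_trajectory(traj, smooth_hz=None)
        np.testing.assert_allclose(out.qddot[2:-2, 0], 2.0, atol=1e-6)

    def test_sine_derivative_accuracy(self):
        t = np.arange(0, 1, 0.01)
        traj = CoordinateTrajectory(time=t, q=np.sin(2 * np.pi * t)[:, None])
        out = differentiate_trajectory(traj, smooth_hz=None)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        err = np.abs(out.qdot[5:-5, 0] - expected[5:-5]).max()
        assert err < 1e-3 * 2 * np.pi

    def test_constant_is_flat(self):
        t = np.arange(0, 1, 0.01)
        traj = CoordinateTrajectory(time=t, q=np.full((t.size, 2), 1.5))
        out = differentiate_trajectory(traj, smooth_hz=None)
        np.testing.assert_allclose(out.qdot, 0.0, atol=1e-11)
        np.testing.assert_allclose(out.qddot, 0.0, atol=1e-9)

    def test_too_few_frames(self):
        traj = CoordinateTrajectory(time=[0.0, 0.01], q=np.zeros((2, 1)))
        with pytest.raises(KinematicsError, match="3 frames"):
            differentiate_trajectory(traj)


class TestAngleComparisons:
    def test_constant_offset_removed(self):
        h = np.linspace(0, 30, 200)
        m, sd = compare_human_robot_angles(h, h + 12.0)
        assert m == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_sinusoidal_difference_mean_abs(self):
        t = np.linspace(0, 2 * np.pi, 20_001)[:-1]  # whole periods
        h = np.zeros_like(t)
        r = h + 12.0 + 1.0 * np.sin(t)
        m, _ = compare_human_robot_angles(h, r)
        assert m == pytest.approx(2 / np.pi, rel=1e-3)  # ~0.64 deg

    def test_length_mismatch(self):
        with pytest.raises(KinematicsError):
            compare_human_robot_angles(np.zeros(3), np.zeros(4))

    def test_encoder_identical_series(self):
        t = np.arange(0, 2, 0.01)
        a = 30 * np.sin(t)
        assert compare_ik_encoder(t, a, t, a) == pytest.approx(0.0, abs=1e-12)

    def test_encoder_white_noise_rms(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 50, 0.01)
        a = 20 * np.sin(t)
        enc = a + 5.0 + rng.normal(0, 2.0, t.size)
        rms = compare_ik_encoder(t, a, t, enc)
        assert rms == pytest.approx(2.0, rel=0.05)

    def test_empty_overlap(self):
        with pytest.raises(KinematicsError, match="overlap"):
            compare_ik_encoder(np.arange(0, 1, 0.1), np.zeros(10),
                               np.arange(5, 6, 0.1), np.zeros(10))
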