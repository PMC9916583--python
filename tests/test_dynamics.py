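"""Inverse dynamics, the forward-dynamics oracle, residual QC,
normalization."""

import math

import numpy as np
import pytest

from conftest import make_chain, make_pendulum
from exogait.dynamics import (DynamicsError, ExternalLoad, check_residuals,
                              forward_dynamics_oracle, inverse_dynamics,
                              kinetic_energy, mass_matrix, normalize_moments,
                              potential_energy)
from exogait.kinematics import CoordinateTrajectory, differentiate_trajectory


def _static_traj(q, n=1):
    q = np.atleast_2d(q)
    q = np.repeat(q, n, axis=0)
    return CoordinateTrajectory(time=np.arange(n) * 0.01 if n > 1 else [0.0],
                                q=q, qdot=np.zeros_like(q),
                                qddot=np.zeros_like(q))


class TestStatics:
    def test_horizontal_pendulum_torque(self):
        m = make_pendulum(mass=2.0, com_offset=0.5)
        gf = inverse_dynamics(m, _static_traj([math.pi / 2]))
        assert abs(gf.tau[0, 0]) == pytest.approx(2 * 9.81 * 0.5, rel=1e-12)

    def test_vertical_pendulum_zero_torque(self):
        m = make_pendulum()
        gf = inverse_dynamics(m, _static_traj([0.0]))
        assert gf.tau[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_static_matches_explicit_lever_arms(self):
        """Independent gravity-balance oracle with explicit moment arms."""
        rng = np.random.default_rng(0)
        m = make_chain(3, rng)
        q = rng.uniform(-1.0, 1.0, 3)
        gf = inverse_dynamics(m, _static_traj(q))
        from exogait.kinematics import forward_kinematics
        fk = forward_kinematics(m, q)
        for ci in range(3):
            axis = fk.coord_axis[ci]
            origin = fk.coord_point[ci]
            tau = 0.0
            for i, seg in enumerate(m.segments.values()):
                if not m.coord_subtree[ci, i]:
                    continue
                com = fk.p[i] + fk.R[i] @ seg.com
                tau += axis @ np.cross(com - origin,
                                       seg.mass * np.array([0, 0, 9.81]))
            assert gf.tau[0, ci] == pytest.approx(tau, rel=1e-9, abs=1e-12)

    def test_missing_accelerations_rejected(self):
        m = make_pendulum()
        traj = CoordinateTrajectory(time=[0.0], q=[[0.0]])
        with pytest.raises(DynamicsError, match="acceleration"):
            inverse_dynamics(m, traj)

    def test_unknown_load_body_rejected(self):
        m = make_pendulum()
        load = ExternalLoad("nope", [0.0], np.zeros((1, 3)),
                            np.zeros((1, 3)), np.zeros((1, 3)))
        with pytest.raises(DynamicsError, match="unknown load body"):
            inverse_dynamics(m, _static_traj([0.0]), [load])


class TestForwardDynamicsOracle:
    def test_energy_conservation(self):
        m = make_pendulum()
        traj = forward_dynamics_oracle(m, [0.5], [0.0], t_span=(0, 10),
                                       t_eval=np.linspace(0, 10, 51))
        E = [kinetic_energy(m, qk, qdk) + potential_energy(m, qk)
             for qk, qdk in zip(traj.q, traj.qdot)]
        assert max(E) - min(E) < 1e-8

    def test_small_angle_period(self):
        m = make_pendulum(mass=2.0, com_offset=0.5)
        I = mass_matrix(m, [0.0])[0, 0]
        expected = 2 * math.pi * math.sqrt(I / (2.0 * 9.81 * 0.5))
        amp = 0.02
        traj = forward_dynamics_oracle(
            m, [amp], [0.0], t_span=(0, 3 * expected),
            t_eval=np.linspace(0, 3 * expected, 3001))
        th = traj.q[:, 0]
        # period from successive positive-going zero crossings
        crossings = np.flatnonzero((th[:-1] < 0) & (th[1:] >= 0))
        periods = np.diff(traj.time[crossings])
        assert periods.mean() == pytest.approx(expected, rel=1e-3)

    def test_zero_state_zero_torque_no_gravity(self):
        m = make_pendulum()
        traj = forward_dynamics_oracle(m, [0.0], [0.0], t_span=(0, 1),
                                       t_eval=np.linspace(0, 1, 11),
                                       gravity=np.zeros(3))
        np.testing.assert_allclose(traj.q, 0.0, atol=1e-12)

    def test_energy_rate_equals_torque_power(self):
        m = make_pendulum()
        tau_fn = lambda t: np.array([0.1 * math.sin(3 * t)])  # noqa: E731
        traj = forward_dynamics_oracle(m, [0.1], [0.0], tau_fn,
                                       t_span=(0, 2),
                                       t_eval=np.linspace(0, 2, 201))
        E = np.array([kinetic_energy(m, qk, qdk) + potential_energy(m, qk)
                      for qk, qdk in zip(traj.q, traj.qdot)])
        dE = np.gradient(E, traj.time)
        power = np.array([tau_fn(t)[0] * qd[0]
                          for t, qd in zip(traj.time, traj.qdot)])
        assert np.abs(dE[2:-2] - power[2:-2]).max() < 5e-4


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_id_recovers_fd_torques(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        m = make_chain(n, rng)
        amps = rng.uniform(0.05, 0.2, n)
        freqs = rng.uniform(0.3, 1.0, n)
        tau_fn = lambda t: amps * np.cos(2 * np.pi * freqs * t)  # noqa: E731
        traj = forward_dynamics_oracle(m, np.zeros(n), np.zeros(n), tau_fn,
                                       t_span=(0, 1.5),
                                       t_eval=np.arange(0, 1.5, 0.01))
        tau_true = np.array([tau_fn(t) for t in traj.time])
        gf = inverse_dynamics(m, traj)
        rel = np.abs(gf.tau - tau_true).max() / np.abs(tau_true).max()
        assert rel < 1e-6

    def test_id_linear_in_loads_and_acceleration(self):
        rng = np.random.default_rng(3)
        m = make_chain(3, rng)
        q = rng.uniform(-0.5, 0.5, 3)
        qd = rng.uniform(-1, 1, 3)

        def gf_of(qdd, scale_load):
            traj = CoordinateTrajectory(time=[0.0], q=[q], qdot=[qd],
                                        qddot=[qdd])
            load = ExternalLoad("link2", [0.0],
                                scale_load * np.array([[10.0, 5.0, -20.0]]),
                                np.array([[0.2, 0.0, -1.0]]),
                                scale_load * np.array([[1.0, 0.0, 0.5]]))
            return inverse_dynamics(m, traj, [load]).tau[0]

        qdd1 = rng.uniform(-2, 2, 3)
        qdd2 = rng.uniform(-2, 2, 3)
        base = gf_of(np.zeros(3), 0.0)
        t1 = gf_of(qdd1, 0.0) - base
        t2 = gf_of(qdd2, 0.0) - base
        t12 = gf_of(qdd1 + qdd2, 0.0) - base
        np.testing.assert_allclose(t12, t1 + t2, rtol=1e-9, atol=1e-12)
        # superposition in external loads at fixed motion
        l1 = gf_of(np.zeros(3), 1.0) - base
        l2 = gf_of(np.zeros(3), 2.0) - base
        np.testing.assert_allclose(l2, 2 * l1, rtol=1e-12, atol=1e-12)

    def test_mass_matrix_symmetric_positive_definite(self):
        rng = np.random.default_rng(4)
        m = make_chain(4, rng)
        M = mass_matrix(m, rng.uniform(-1, 1, 4))
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert np.linalg.eigvalsh(M).min() > 0


class TestResiduals:
    def test_standing_without_loads_shows_weight(self, lumped):
        q = np.zeros(lumped.n_coordinates)
        q[2] = 0.95
        traj = _static_traj(q)
        gf = inverse_dynamics(lumped, traj)
        report = check_residuals(gf, lumped, traj)
        weight = lumped.total_mass * 9.81
        # unsupported body: vertical residual is exactly the model weight
        assert abs(gf.residuals[0, 2]) == pytest.approx(weight, rel=1e-12)
        assert report.max_mismatch < 1e-9 * weight

    def test_doubled_loads_flip_residual(self, lumped):
        q = np.zeros(lumped.n_coordinates)
        q[2] = 0.95
        traj = _static_traj(q)
        weight = lumped.total_mass * 9.81
        for scale, expected in ((1.0, 0.0), (2.0, -weight)):
            loads = [ExternalLoad(body, [0.0],
                                  np.array([[0, 0, scale * weight / 2]]),
                                  np.zeros((1, 3)), np.zeros((1, 3)))
                     for body in ("calcn_l", "calcn_r")]
            gf = inverse_dynamics(lumped, traj, loads)
            assert gf.residuals[0, 2] == pytest.approx(expected,
                                                       abs=1e-9 * weight)


class TestNormalization:
    def test_unassisted_uses_subject_mass(self):
        gf = _dummy_gf(19.62)
        nm = normalize_moments(gf, "unassisted", subject_mass=89.4)
        assert nm.tau_norm[0, 0] == pytest.approx(0.2195, abs=5e-5)

    def test_round_trip(self):
        gf = _dummy_gf(42.0)
        nm = normalize_moments(gf, "assisted", subject_mass=89.4,
                               exo_mass=23.0)
        np.testing.assert_allclose(nm.denormalize(), gf.tau, rtol=1e-12)

    def test_zero_exo_mass_equals_unassisted(self):
        gf = _dummy_gf(10.0)
        a = normalize_moments(gf, "assisted", 89.4, exo_mass=0.0)
        u = normalize_moments(gf, "unassisted", 89.4)
        np.testing.assert_allclose(a.tau_norm, u.tau_norm)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(DynamicsError):
            normalize_moments(_dummy_gf(1.0), "assisted", 0.0)


def _dummy_gf(value):
    from exogait.dynamics import GeneralizedForces
    return GeneralizedForces(time=np.array([0.0]),
                             tau=np.array([[value]]),
                             coordinate_names=["theta"],
                             base_coordinates=[])
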