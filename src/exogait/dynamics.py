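"""Inverse dynamics, a forward-dynamics oracle, and moment normalization.

Inverse dynamics solves, per frame,

    tau = sum_i [ Jv_i^T m_i (a_ci - g) + Jw_i^T (I_i alpha_i + w_i x I_i w_i) ]
          - sum_ext [ Jp^T F_ext + Jw^T M_free ]

which is the Newton-Euler balance of every body mapped to generalized
coordinates through the geometric Jacobians — algebraically identical to the
recursive formulation on a tree.  Body angular velocity/acceleration and COM
acceleration are propagated exactly along the compiled primitive chains from
(q, qdot, qddot).  External ground loads are applied as a force at the center
of pressure plus a free moment.  The six base (ground-to-pelvis) generalized
forces are not joint moments: they are the dynamic residuals, reported
separately as a consistency diagnostic.

The forward-dynamics oracle inverts the same equations (mass matrix assembled
column-wise by unit-acceleration inverse-dynamics calls) and integrates them
with a high-order adaptive scheme; it exists to verify inverse dynamics by
round trip on small chains and is not meant for the full 37-DoF model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._transforms import rotation_about_axis
from .kinematics import (CoordinateTrajectory, FKState, angular_jacobian,
                         forward_kinematics, point_jacobian)
from .model import MultibodyModel

GRAVITY = np.array([0.0, 0.0, -9.81])


class DynamicsError(ValueError):
    pass


@dataclass
class ExternalLoad:
    """A ground (or other external) load applied to one body over time."""

    body: str
    time: np.ndarray
    force: np.ndarray        # (T, 3) N, world frame
    cop: np.ndarray          # (T, 3) m, world frame point of application
    free_moment: np.ndarray  # (T, 3) N*m, world frame

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.force = np.asarray(self.force, float)
        self.cop = np.asarray(self.cop, float)
        self.free_moment = np.asarray(self.free_moment, float)
        T = self.time.size
        for name in ("force", "cop", "free_moment"):
            arr = getattr(self, name)
            if arr.shape != (T, 3):
                raise DynamicsError(f"load {self.body}: {name} must be (T, 3)")
            if not np.all(np.isfinite(arr)):
                raise DynamicsError(f"load {self.body}: non-finite {name}")


@dataclass
class GeneralizedForces:
    """Per-coordinate generalized forces; base entries reported as residuals."""

    time: np.ndarray
    tau: np.ndarray
    coordinate_names: list[str]
    base_coordinates: list[int]

    @property
    def residuals(self) -> np.ndarray:
        """Generalized forces on the unactuated base coordinates, (T, 6)."""
        return self.tau[:, self.base_coordinates]

    def joint_moments(self) -> np.ndarray:
        """tau with the base columns zeroed out (net joint moments only)."""
        out = self.tau.copy()
        out[:, self.base_coordinates] = 0.0
        return out

    def column(self, name: str) -> np.ndarray:
        return self.tau[:, self.coordinate_names.index(name)]


@dataclass
class NormalizedMoments:
    tau_norm: np.ndarray
    normalizing_mass: float
    condition: str
    coordinate_names: list[str]

    def denormalize(self) -> np.ndarray:
        return self.tau_norm * self.normalizing_mass


# ---------------------------------------------------------------------------
# exact body-kinematics propagation
# ---------------------------------------------------------------------------

class BodyKinematics:
    __slots__ = ("fk", "omega", "alpha", "v_com", "a_com", "com")

    def __init__(self, n_segments):
        self.omega = np.zeros((n_segments, 3))
        self.alpha = np.zeros((n_segments, 3))
        self.v_com = np.zeros((n_segments, 3))
        self.a_com = np.zeros((n_segments, 3))
        self.com = np.zeros((n_segments, 3))
        self.fk = None


def body_kinematics(model: MultibodyModel, q, qdot, qddot) -> BodyKinematics:
    """Propagate poses, angular velocity/acceleration, and COM acceleration."""
    q = np.asarray(q, float)
    qdot = np.asarray(qdot, float)
    qddot = np.asarray(qddot, float)
    bk = BodyKinematics(model.n_segments)
    fk = FKState(model.n_segments, model.n_coordinates)
    # per-segment state of the frame origin
    v_o = np.zeros((model.n_segments, 3))
    a_o = np.zeros((model.n_segments, 3))
    for joint, child_idx, parent_idx, prims in model._chains:
        if parent_idx is None:
            R, p = np.eye(3), np.zeros(3)
            w, al = np.zeros(3), np.zeros(3)
            v, a = np.zeros(3), np.zeros(3)
        else:
            R, p = fk.R[parent_idx].copy(), fk.p[parent_idx].copy()
            w, al = bk.omega[parent_idx].copy(), bk.alpha[parent_idx].copy()
            v, a = v_o[parent_idx].copy(), a_o[parent_idx].copy()
        for prim in prims:
            kind = prim[0]
            if kind == "fixed":
                _, Rf, t = prim
                d = R @ t
                p = p + d
                v = v + np.cross(w, d)
                a = a + np.cross(al, d) + np.cross(w, np.cross(w, d))
                R = R @ Rf
            elif kind == "rev":
                _, ax, ci = prim
                u = R @ ax
                fk.coord_kind[ci] = "rev"
                fk.coord_axis[ci] = u
                fk.coord_point[ci] = p
                al = al + qddot[ci] * u + np.cross(w, qdot[ci] * u)
                w = w + qdot[ci] * u
                R = R @ rotation_about_axis(ax, q[ci])
            elif kind == "trans":
                _, ax, ci = prim
                u = R @ ax
                fk.coord_kind[ci] = "trans"
                fk.coord_axis[ci] = u
                fk.coord_point[ci] = p
                d = q[ci] * u
                p = p + d
                a = (a + qddot[ci] * u + 2.0 * np.cross(w, qdot[ci] * u)
                     + np.cross(al, d) + np.cross(w, np.cross(w, d)))
                v = v + qdot[ci] * u + np.cross(w, d)
            else:  # ctrans
                _, f, df, d2f, ci = prim
                d_l = f(q[ci])
                v_l = df(q[ci]) * qdot[ci]
                a_l = d2f(q[ci]) * qdot[ci] ** 2 + df(q[ci]) * qddot[ci]
                fk.coord_lin[ci] = R @ df(q[ci])
                d = R @ d_l
                p = p + d
                a = (a + R @ a_l + 2.0 * np.cross(w, R @ v_l)
                     + np.cross(al, d) + np.cross(w, np.cross(w, d)))
                v = v + R @ v_l + np.cross(w, d)
        fk.R[child_idx] = R
        fk.p[child_idx] = p
        bk.omega[child_idx] = w
        bk.alpha[child_idx] = al
        v_o[child_idx] = v
        a_o[child_idx] = a
    # COM kinematics
    for i, seg in enumerate(model.segments.values()):
        r = fk.R[i] @ seg.com
        bk.com[i] = fk.p[i] + r
        bk.v_com[i] = v_o[i] + np.cross(bk.omega[i], r)
        bk.a_com[i] = (a_o[i] + np.cross(bk.alpha[i], r)
                       + np.cross(bk.omega[i], np.cross(bk.omega[i], r)))
    if model.n_markers:
        Rm = fk.R[model.marker_segment]
        fk.markers = fk.p[model.marker_segment] + \
            np.einsum("mij,mj->mi", Rm, model.marker_locals)
    bk.fk = fk
    return bk


def _frame_tau(model: MultibodyModel, bk: BodyKinematics,
               masses: np.ndarray, inertias: np.ndarray,
               gravity: np.ndarray,
               loads_at_frame: list[tuple[int, np.ndarray, np.ndarray,
                                          np.ndarray]]) -> np.ndarray:
    fk = bk.fk
    seg_idx = np.arange(model.n_segments)
    # body wrenches about their own COMs
    F = masses[:, None] * (bk.a_com - gravity)
    Iw = np.einsum("sij,sjk,slk->sil", fk.R, inertias, fk.R)
    M = (np.einsum("sij,sj->si", Iw, bk.alpha)
         + np.cross(bk.omega, np.einsum("sij,sj->si", Iw, bk.omega)))
    Jv = point_jacobian(model, fk, bk.com, seg_idx)
    Jw = angular_jacobian(model, fk, seg_idx)
    tau = (np.einsum("sic,si->c", Jv, F) + np.einsum("sic,si->c", Jw, M))
    for bidx, f_ext, p_ext, m_ext in loads_at_frame:
        Jp = point_jacobian(model, fk, p_ext[None, :],
                            np.array([bidx]))[0]
        Jwb = angular_jacobian(model, fk, np.array([bidx]))[0]
        tau -= Jp.T @ f_ext + Jwb.T @ m_ext
    return tau


def inverse_dynamics(model: MultibodyModel, traj: CoordinateTrajectory,
                     loads: list[ExternalLoad] | None = None,
                     gravity: np.ndarray = GRAVITY) -> GeneralizedForces:
    """Net generalized forces from kinematics, inertia, and external loads.

    Requires ``traj.qdot`` and ``traj.qddot`` (use
    :func:`~exogait.kinematics.differentiate_trajectory` or exact generator
    derivatives).  External wrenches are applied at the COP with the free
    moment; unknown load bodies raise.
    """
    if traj.qdot is None or traj.qddot is None:
        raise DynamicsError("trajectory is missing velocities/accelerations")
    loads = loads or []
    for ld in loads:
        if ld.body not in model.segment_index:
            raise DynamicsError(f"unknown load body {ld.body!r}")
    gravity = np.asarray(gravity, float)
    masses = np.array([s.mass for s in model.segments.values()])
    inertias = np.array([s.inertia for s in model.segments.values()])
    T = traj.n_frames
    tau = np.zeros((T, model.n_coordinates))
    # loads resampled to the trajectory clock
    load_arrays = []
    for ld in loads:
        bidx = model.segment_index[ld.body]
        cols = []
        for arr in (ld.force, ld.cop, ld.free_moment):
            cols.append(np.column_stack(
                [np.interp(traj.time, ld.time, arr[:, k]) for k in range(3)]))
        load_arrays.append((bidx, *cols))
    for t in range(T):
        bk = body_kinematics(model, traj.q[t], traj.qdot[t], traj.qddot[t])
        frame_loads = [(b, f[t], p[t], m[t]) for b, f, p, m in load_arrays]
        tau[t] = _frame_tau(model, bk, masses, inertias, gravity, frame_loads)
    return GeneralizedForces(time=traj.time, tau=tau,
                             coordinate_names=list(model.coordinate_names),
                             base_coordinates=list(model.base_coordinates))


# ---------------------------------------------------------------------------
# forward-dynamics oracle (verification only; small models)
# ---------------------------------------------------------------------------

def _id_point(model, q, qdot, qddot, gravity, masses, inertias, loads):
    bk = body_kinematics(model, q, qdot, qddot)
    return _frame_tau(model, bk, masses, inertias, gravity, loads)


def mass_matrix(model: MultibodyModel, q: np.ndarray,
                masses=None, inertias=None) -> np.ndarray:
    """Joint-space mass matrix from body Jacobians:
    ``M = sum_i Jv_i^T m_i Jv_i + Jw_i^T I_i Jw_i``."""
    if masses is None:
        masses = np.array([s.mass for s in model.segments.values()])
        inertias = np.array([s.inertia for s in model.segments.values()])
    fk = forward_kinematics(model, q)
    coms = np.array([fk.p[i] + fk.R[i] @ s.com
                     for i, s in enumerate(model.segments.values())])
    seg_idx = np.arange(model.n_segments)
    Jv = point_jacobian(model, fk, coms, seg_idx)
    Jw = angular_jacobian(model, fk, seg_idx)
    Iw = np.einsum("sij,sjk,slk->sil", fk.R, inertias, fk.R)
    M = (np.einsum("sic,s,sid->cd", Jv, masses, Jv)
         + np.einsum("sic,sij,sjd->cd", Jw, Iw, Jw))
    return 0.5 * (M + M.T)


def forward_dynamics_oracle(model: MultibodyModel, q0: np.ndarray,
                            qdot0: np.ndarray, tau_fn=None,
                            t_span: tuple[float, float] = (0.0, 1.0),
                            t_eval: np.ndarray | None = None,
                            gravity: np.ndarray = GRAVITY,
                            rtol: float = 1e-10,
                            atol: float = 1e-12) -> CoordinateTrajectory:
    """Integrate M(q) qddot = tau - bias for small chains (testing oracle).

    ``tau_fn(t) -> (n,)`` supplies applied generalized forces (default zero).
    Returns a trajectory whose ``qddot`` are the exact accelerations evaluated
    from the equations of motion at the sample times.
    """
    n = model.n_coordinates
    if n > 10:
        warnings.warn("forward_dynamics_oracle is intended for small models "
                      f"(<= 10 DoF); got {n}")
    gravity = np.asarray(gravity, float)
    masses = np.array([s.mass for s in model.segments.values()])
    inertias = np.array([s.inertia for s in model.segments.values()])
    if tau_fn is None:
        tau_fn = lambda t: np.zeros(n)  # noqa: E731

    def qddot_of(t, q, qd):
        bias = _id_point(model, q, qd, np.zeros(n), gravity, masses, inertias,
                         [])
        M = mass_matrix(model, q, masses, inertias)
        return np.linalg.solve(M, tau_fn(t) - bias)

    def rhs(t, y):
        q, qd = y[:n], y[n:]
        return np.concatenate([qd, qddot_of(t, q, qd)])

    y0 = np.concatenate([np.asarray(q0, float), np.asarray(qdot0, float)])
    sol = solve_ivp(rhs, t_span, y0, method="DOP853", rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=t_eval is None)
    if not sol.success:
        raise DynamicsError(f"forward dynamics integration failed: {sol.message}")
    t = sol.t
    q = sol.y[:n].T
    qd = sol.y[n:].T
    qdd = np.array([qddot_of(ti, qi, qdi) for ti, qi, qdi in zip(t, q, qd)])
    return CoordinateTrajectory(time=t, q=q, qdot=qd, qddot=qdd,
                                coordinate_names=list(model.coordinate_names))


def kinetic_energy(model: MultibodyModel, q, qdot) -> float:
    M = mass_matrix(model, q)
    qdot = np.asarray(qdot, float)
    return float(0.5 * qdot @ M @ qdot)


def potential_energy(model: MultibodyModel, q,
                     gravity: np.ndarray = GRAVITY) -> float:
    fk = forward_kinematics(model, q)
    pe = 0.0
    for i, seg in enumerate(model.segments.values()):
        com = fk.p[i] + fk.R[i] @ seg.com
        pe -= seg.mass * float(np.asarray(gravity, float) @ com)
    return pe


# ---------------------------------------------------------------------------
# residual QC and normalization
# ---------------------------------------------------------------------------

@dataclass
class ResidualReport:
    max_force: float          # max |base translational residual|, N
    max_force_fraction: float  # as a fraction of model weight
    residual_force: np.ndarray  # (T, 3)
    expected_force: np.ndarray  # (T, 3) whole-body Newton balance
    max_mismatch: float       # max |residual - expected|, N

    def __str__(self):  # pragma: no cover - cosmetic
        return (f"max base residual force {self.max_force:.3g} N "
                f"({self.max_force_fraction:.3g} of model weight), "
                f"Newton-balance mismatch {self.max_mismatch:.3g} N")


def check_residuals(gf: GeneralizedForces, model: MultibodyModel,
                    traj: CoordinateTrajectory,
                    loads: list[ExternalLoad] | None = None,
                    gravity: np.ndarray = GRAVITY) -> ResidualReport:
    """Whole-body Newton consistency of the base residual forces.

    The translational base residuals must equal
    ``total_mass * (a_com - g) - sum(F_ext)`` frame by frame; large values
    indicate inconsistent loads, kinematics, or unmeasured external forces
    (e.g. crutches).
    """
    gravity = np.asarray(gravity, float)
    loads = loads or []
    masses = np.array([s.mass for s in model.segments.values()])
    total = masses.sum()
    kinds = model.coordinate_kinds()
    trans_base = [ci for ci in gf.base_coordinates
                  if kinds[ci] == "translation"]
    resid = gf.tau[:, trans_base]
    T = traj.n_frames
    expected = np.zeros((T, 3))
    for t in range(T):
        bk = body_kinematics(model, traj.q[t], traj.qdot[t], traj.qddot[t])
        f_ext = np.zeros(3)
        for ld in loads:
            f_ext += np.column_stack(
                [np.interp(traj.time[t], ld.time, ld.force[:, k])
                 for k in range(3)])[0]
        expected[t] = masses @ bk.a_com - total * gravity - f_ext
    weight = total * np.linalg.norm(gravity)
    max_force = float(np.abs(resid).max()) if resid.size else 0.0
    mismatch = float(np.abs(resid - expected).max()) if resid.size else 0.0
    return ResidualReport(max_force=max_force,
                          max_force_fraction=max_force / weight,
                          residual_force=resid, expected_force=expected,
                          max_mismatch=mismatch)


def normalize_moments(gf: GeneralizedForces, condition: str,
                      subject_mass: float,
                      exo_mass: float = 0.0) -> NormalizedMoments:
    """Normalize joint moments to body (or body+device) mass.

    Assisted locomotion divides by the combined participant + exoskeleton
    mass; unassisted divides by the participant's mass alone.
    """
    if condition not in ("assisted", "unassisted"):
        raise DynamicsError(f"unknown condition {condition!r}")
    if subject_mass <= 0 or exo_mass < 0:
        raise DynamicsError("masses must be positive")
    mass = subject_mass + exo_mass if condition == "assisted" else subject_mass
    return NormalizedMoments(tau_norm=gf.tau / mass, normalizing_mass=mass,
                             condition=condition,
                             coordinate_names=list(gf.coordinate_names))
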