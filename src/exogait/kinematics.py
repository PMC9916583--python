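"""Forward and inverse kinematics.

Forward kinematics composes the compiled primitive chains of a
:class:`~exogait.model.MultibodyModel` and, as a by-product, records the world
axis and anchor point of every generalized coordinate, from which marker and
body Jacobians follow geometrically (revolute column: ``u x (p - o)``;
prismatic column: ``u``).  Inverse kinematics is a per-frame weighted
least-squares fit of the model markers to the observed markers, solved by
damped Gauss-Newton with a Levenberg-style adaptation, warm-started from the
previous frame.  Occluded markers are dropped from the frame objective;
coordinates with no visible marker anywhere in their subtree are flagged
unobservable and held at the warm start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from ._transforms import rotation_about_axis
from .model import GROUND, MultibodyModel


class KinematicsError(ValueError):
    pass


@dataclass
class CoordinateTrajectory:
    """Generalized coordinates over time (rad / m), optional derivatives."""

    time: np.ndarray
    q: np.ndarray
    qdot: np.ndarray | None = None
    qddot: np.ndarray | None = None
    coordinate_names: list[str] | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != self.time.size:
            raise KinematicsError("q must be (n_frames, n_coordinates)")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise KinematicsError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def column(self, name: str) -> np.ndarray:
        if self.coordinate_names is None:
            raise KinematicsError("trajectory has no coordinate names")
        return self.q[:, self.coordinate_names.index(name)]


@dataclass
class MarkerTrajectorySet:
    """Time-stamped marker clouds with per-frame occlusion flags."""

    time: np.ndarray
    markers: dict[str, np.ndarray]
    occluded: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        for name, pos in self.markers.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (self.time.size, 3):
                raise KinematicsError(f"marker {name}: positions must be (T, 3)")
            self.markers[name] = pos
            if name not in self.occluded:
                self.occluded[name] = np.any(~np.isfinite(pos), axis=1)
            else:
                self.occluded[name] = np.asarray(self.occluded[name], bool)

    @property
    def n_frames(self) -> int:
        return self.time.size

    def to_arrays(self, marker_names: list[str]):
        """Stack into (T, M, 3) positions and (T, M) visibility for a given
        marker ordering; markers absent from the set are never visible."""
        T = self.n_frames
        P = np.full((T, len(marker_names), 3), np.nan)
        vis = np.zeros((T, len(marker_names)), dtype=bool)
        for k, name in enumerate(marker_names):
            if name in self.markers:
                P[:, k] = self.markers[name]
                vis[:, k] = ~self.occluded[name]
        vis &= np.all(np.isfinite(P), axis=2)
        return P, vis


class FKState:
    """Body poses, marker positions, and per-coordinate geometric data."""

    __slots__ = ("R", "p", "markers", "coord_kind", "coord_axis",
                 "coord_point", "coord_lin")

    def __init__(self, n_segments, n_coordinates):
        self.R = np.zeros((n_segments, 3, 3))
        self.p = np.zeros((n_segments, 3))
        self.markers = None
        self.coord_kind = [""] * n_coordinates
        self.coord_axis = np.zeros((n_coordinates, 3))
        self.coord_point = np.zeros((n_coordinates, 3))
        self.coord_lin = np.zeros((n_coordinates, 3))  # coupled-translation term


def forward_kinematics(model: MultibodyModel, q: np.ndarray) -> FKState:
    """Compose body poses and marker positions for one coordinate vector."""
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_coordinates,):
        raise KinematicsError(
            f"q has dimension {q.shape}, expected ({model.n_coordinates},)")
    fk = FKState(model.n_segments, model.n_coordinates)
    for joint, child_idx, parent_idx, prims in model._chains:
        if parent_idx is None:
            R = np.eye(3)
            p = np.zeros(3)
        else:
            R = fk.R[parent_idx]
            p = fk.p[parent_idx]
        for prim in prims:
            kind = prim[0]
            if kind == "fixed":
                _, Rf, t = prim
                p = p + R @ t
                R = R @ Rf
            elif kind == "rev":
                _, ax, ci = prim
                u = R @ ax
                fk.coord_kind[ci] = "rev"
                fk.coord_axis[ci] = u
                fk.coord_point[ci] = p
                R = R @ rotation_about_axis(ax, q[ci])
            elif kind == "trans":
                _, ax, ci = prim
                u = R @ ax
                fk.coord_kind[ci] = "trans"
                fk.coord_axis[ci] = u
                fk.coord_point[ci] = p
                p = p + q[ci] * u
            else:  # ctrans: knee-coupled prescribed translation
                _, f, df, _, ci = prim
                fk.coord_lin[ci] = R @ df(q[ci])
                p = p + R @ f(q[ci])
        fk.R[child_idx] = R
        fk.p[child_idx] = p
    if model.n_markers:
        Rm = fk.R[model.marker_segment]
        fk.markers = fk.p[model.marker_segment] + \
            np.einsum("mij,mj->mi", Rm, model.marker_locals)
    else:
        fk.markers = np.zeros((0, 3))
    return fk


def marker_jacobian(model: MultibodyModel, fk: FKState) -> np.ndarray:
    """d(marker positions)/d(q), shape (n_markers, 3, n_coordinates)."""
    J = np.zeros((model.n_markers, 3, model.n_coordinates))
    P = fk.markers
    for ci in range(model.n_coordinates):
        mask = model.coord_marker_mask[ci]
        if not mask.any():
            continue
        u = fk.coord_axis[ci]
        if fk.coord_kind[ci] == "rev":
            J[mask, :, ci] = np.cross(u, P[mask] - fk.coord_point[ci])
            lin = fk.coord_lin[ci]
            if lin.any():
                J[mask, :, ci] += lin
        else:
            J[mask, :, ci] = u
    return J


def point_jacobian(model: MultibodyModel, fk: FKState, points: np.ndarray,
                   seg_idx: np.ndarray) -> np.ndarray:
    """Jacobian of world points attached to segments, (K, 3, C)."""
    K = points.shape[0]
    J = np.zeros((K, 3, model.n_coordinates))
    sub = model.coord_subtree[:, seg_idx]  # (C, K)
    for ci in range(model.n_coordinates):
        mask = sub[ci]
        if not mask.any():
            continue
        u = fk.coord_axis[ci]
        if fk.coord_kind[ci] == "rev":
            J[mask, :, ci] = np.cross(u, points[mask] - fk.coord_point[ci])
            lin = fk.coord_lin[ci]
            if lin.any():
                J[mask, :, ci] += lin
        else:
            J[mask, :, ci] = u
    return J


def angular_jacobian(model: MultibodyModel, fk: FKState,
                     seg_idx: np.ndarray) -> np.ndarray:
    """Angular-velocity Jacobian of segments, (K, 3, C)."""
    K = seg_idx.shape[0]
    J = np.zeros((K, 3, model.n_coordinates))
    sub = model.coord_subtree[:, seg_idx]
    for ci in range(model.n_coordinates):
        if fk.coord_kind[ci] != "rev":
            continue
        mask = sub[ci]
        if mask.any():
            J[mask, :, ci] = fk.coord_axis[ci]
    return J


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

@dataclass
class IKFrameResult:
    q: np.ndarray
    rms: float
    converged: bool
    n_iter: int
    under_determined: bool
    unobservable: list[int]
    marker_errors: np.ndarray  # per-marker distances, nan when not visible


@dataclass
class IKResult:
    trajectory: CoordinateTrajectory
    per_frame_rms: np.ndarray
    mean_rms: float
    rms_sd: float
    worst_marker: str | None
    worst_marker_error: float
    rms_tolerance: float
    passed: bool
    converged: np.ndarray
    under_determined_frames: list[int]


def solve_ik_frame(model: MultibodyModel, positions: np.ndarray,
                   visible: np.ndarray, q_init: np.ndarray,
                   weights: np.ndarray | None = None,
                   max_iter: int = 100, step_tol: float = 1e-8,
                   obj_tol: float = 1e-12,
                   lam0: float = 1e-3) -> IKFrameResult:
    """Fit model coordinates to one frame of observed markers.

    ``positions`` is (n_markers, 3) in the model's marker order; ``visible``
    masks occluded/missing markers out of the objective.
    """
    if weights is None:
        weights = model.marker_weights
    visible = np.asarray(visible, bool) & (weights > 0)
    unobservable = [ci for ci in range(model.n_coordinates)
                    if not (model.coord_marker_mask[ci] & visible).any()]
    free = np.array([ci not in set(unobservable)
                     for ci in range(model.n_coordinates)])
    n_free = int(free.sum())
    under = 3 * int(visible.sum()) < n_free
    w = np.repeat(weights[visible], 3)
    wsum = float(weights[visible].sum())

    q = np.asarray(q_init, dtype=float).copy()
    fk = forward_kinematics(model, q)
    res = (positions[visible] - fk.markers[visible]).ravel()
    obj = float(np.dot(w * res, res))
    lam = lam0
    converged = False
    it = 0
    if n_free > 0 and visible.any():
        for it in range(1, max_iter + 1):
            J = marker_jacobian(model, fk)[visible].reshape(-1,
                                                            model.n_coordinates)
            J = J[:, free]
            A = (J * w[:, None]).T @ J
            g = (J * w[:, None]).T @ res
            accepted = False
            for _ in range(25):
                try:
                    dq = np.linalg.solve(A + lam * np.eye(n_free), g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                q_try = q.copy()
                q_try[free] += dq
                fk_try = forward_kinematics(model, q_try)
                res_try = (positions[visible] - fk_try.markers[visible]).ravel()
                obj_try = float(np.dot(w * res_try, res_try))
                if obj_try <= obj:
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
            delta_obj = obj - obj_try
            q, fk, res, obj = q_try, fk_try, res_try, obj_try
            lam = max(lam * 0.3, 1e-12)
            if np.max(np.abs(dq)) < step_tol or delta_obj < obj_tol:
                converged = True
                break
    else:
        converged = True

    errs = np.full(model.n_markers, np.nan)
    if visible.any():
        errs[visible] = np.linalg.norm(positions[visible] - fk.markers[visible],
                                       axis=1)
        # weighted RMS of per-marker distances
        rms = float(np.sqrt(np.sum(weights[visible] * errs[visible] ** 2)
                            / wsum)) if wsum > 0 else 0.0
    else:
        rms = float("nan")
    return IKFrameResult(q=q, rms=rms, converged=converged, n_iter=it,
                         under_determined=under, unobservable=unobservable,
                         marker_errors=errs)


def _coarse_root_fit(model: MultibodyModel, positions, visible, q):
    """Initialize the six base coordinates from the root-segment markers."""
    base = model.base_joint
    if base.type != "universal6":
        return q
    root_idx = model.segment_index[model.root]
    on_root = (model.marker_segment == root_idx) & visible
    if on_root.sum() < 3:
        return q
    fk0 = forward_kinematics(model, q)
    X = fk0.markers[on_root]
    Y = positions[on_root]
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    H = (X - cx).T @ (Y - cy)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    Rstar = Vt.T @ D @ U.T
    R0 = fk0.R[root_idx]
    p_new = Rstar @ (fk0.p[root_idx] - cx) + cy
    q = q.copy()
    ci0 = model.base_coordinates[0]
    q[ci0:ci0 + 3] = p_new - base.parent_rotation @ base.parent_offset
    if np.allclose(base.axes, np.eye(3)):
        try:
            ang = Rotation.from_matrix(Rstar @ R0).as_euler("XYZ")
            q[ci0 + 3:ci0 + 6] = ang
        except ValueError:  # pragma: no cover - degenerate rotation
            pass
    return q


def solve_ik(model: MultibodyModel, markers: MarkerTrajectorySet,
             weights: np.ndarray | None = None,
             q0: np.ndarray | None = None,
             rms_tolerance: float = 0.02, **frame_opts) -> IKResult:
    """Frame-sequential IK over a trial with previous-frame warm start.

    ``rms_tolerance`` is the pass/fail bound on the mean marker RMS error
    (default 2 cm, the standard acceptance threshold for marker tracking).
    """
    if markers.n_frames == 0:
        raise KinematicsError("empty marker trajectory")
    P, vis = markers.to_arrays(model.marker_names)
    T = markers.n_frames
    q = model.neutral_pose() if q0 is None else np.asarray(q0, float).copy()
    if q0 is None:
        q = _coarse_root_fit(model, P[0], vis[0], q)
    Q = np.zeros((T, model.n_coordinates))
    rms = np.zeros(T)
    conv = np.zeros(T, dtype=bool)
    under = []
    worst_err = -1.0
    worst_name = None
    for t in range(T):
        fr = solve_ik_frame(model, P[t], vis[t], q, weights=weights,
                            **frame_opts)
        q = fr.q
        Q[t] = q
        rms[t] = fr.rms
        conv[t] = fr.converged
        if fr.under_determined:
            under.append(t)
        if np.any(np.isfinite(fr.marker_errors)):
            k = int(np.nanargmax(fr.marker_errors))
            if fr.marker_errors[k] > worst_err:
                worst_err = float(fr.marker_errors[k])
                worst_name = model.marker_names[k]
    good = np.isfinite(rms)
    mean_rms = float(np.mean(rms[good])) if good.any() else float("nan")
    rms_sd = float(np.std(rms[good], ddof=1)) if good.sum() > 1 else 0.0
    traj = CoordinateTrajectory(time=markers.time, q=Q,
                                coordinate_names=list(model.coordinate_names))
    return IKResult(trajectory=traj, per_frame_rms=rms, mean_rms=mean_rms,
                    rms_sd=rms_sd, worst_marker=worst_name,
                    worst_marker_error=worst_err,
                    rms_tolerance=rms_tolerance,
                    passed=bool(mean_rms < rms_tolerance),
                    converged=conv, under_determined_frames=under)


# ---------------------------------------------------------------------------
# differentiation and angle comparisons
# ---------------------------------------------------------------------------

def differentiate_trajectory(traj: CoordinateTrajectory,
                             smooth_hz: float | None = 6.0,
                             order: int = 4) -> CoordinateTrajectory:
    """Low-pass (zero-phase, default 6 Hz / 4th order) then differentiate.

    Central differences at interior frames, one-sided at the ends; pass
    ``smooth_hz=None`` to differentiate the raw coordinates.
    """
    if traj.n_frames < 3:
        raise KinematicsError("need at least 3 frames to differentiate")
    dt = np.diff(traj.time)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise KinematicsError("differentiation requires uniform sampling")
    fs = 1.0 / dt[0]
    q = traj.q
    if smooth_hz is not None:
        sos = butter(order, smooth_hz, btype="low", fs=fs, output="sos")
        q = sosfiltfilt(sos, q, axis=0)
    qdot = np.gradient(q, traj.time, axis=0, edge_order=2)
    qddot = np.gradient(qdot, traj.time, axis=0, edge_order=2)
    return CoordinateTrajectory(time=traj.time, q=q, qdot=qdot, qddot=qddot,
                                coordinate_names=traj.coordinate_names)


def compare_human_robot_angles(human: np.ndarray,
                               robot: np.ndarray) -> tuple[float, float]:
    """Mean +/- SD absolute angle difference after constant-offset removal.

    The offset between the two segment coordinate frames is taken as the
    trial-mean difference; returns (mean |h - r - offset|, SD) in the input
    units (degrees at the reporting layer).
    """
    human = np.asarray(human, float)
    robot = np.asarray(robot, float)
    if human.shape != robot.shape:
        raise KinematicsError("angle series length mismatch")
    d = human - robot
    d = np.abs(d - d.mean())
    return float(d.mean()), float(d.std(ddof=0))


def compare_ik_encoder(ik_time: np.ndarray, ik_angle: np.ndarray,
                       enc_time: np.ndarray, enc_angle: np.ndarray) -> float:
    """RMS difference between IK and encoder joint angles (offset removed).

    The encoder stream is linearly resampled onto the IK time base over the
    overlapping window before comparison.
    """
    ik_time = np.asarray(ik_time, float)
    enc_time = np.asarray(enc_time, float)
    t0 = max(ik_time[0], enc_time[0])
    t1 = min(ik_time[-1], enc_time[-1])
    sel = (ik_time >= t0) & (ik_time <= t1)
    if not sel.any():
        raise KinematicsError("empty overlap window between IK and encoder")
    enc = np.interp(ik_time[sel], enc_time, np.asarray(enc_angle, float))
    d = np.asarray(ik_angle, float)[sel] - enc
    d = d - d.mean()
    return float(np.sqrt(np.mean(d ** 2)))
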