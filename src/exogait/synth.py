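"""Synthetic trial generation with known ground truth.

Every stage of the pipeline (IK, ID, events, EMG, reporting) is tested
against trials generated here.  Joint trajectories are idealized smooth
periodic waveforms (cosine harmonics with analytic first and second
derivatives), not captured human curves: the point is exact parameter
recovery, not physiological realism.  Default amplitudes and speeds encode
the two study conditions — powered exoskeletal-assisted walking (0.47 m/s,
peak knee flexion 50.1 deg, flexed hips, minimal push-off ankle range, with
the exoskeleton hip/knee pins driven to the same angles as the human joints)
and unassisted walking (1.11 m/s, peak knee flexion 68.6 deg, full hip
extension, larger ankle excursion).

Ground loads are constructed to be dynamically consistent: the whole-body
Newton-Euler resultant wrench required by the commanded accelerations is
distributed between the feet by a raised-cosine stance-weight blend (10% of
the cycle of double support; single support gives one foot everything), with
the force applied at a COP under the stance foot and the moment balance
closed by a free moment.  Inverse dynamics on these loads therefore returns
near-zero base residuals, which is the acceptance surface for the dynamics
chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import GRAVITY, ExternalLoad, body_kinematics, inverse_dynamics
from .kinematics import (CoordinateTrajectory, MarkerTrajectorySet,
                         forward_kinematics)
from .model import (MultibodyModel, SubjectAnthropometry,
                    build_exoskeleton_model, build_human_model, couple_models,
                    default_subject, lump_exoskeleton_inertia, scale_model)

DEG = math.pi / 180.0

MUSCLES = ["rectus_femoris", "vastus_lateralis", "vastus_medialis",
           "semitendinosus", "biceps_femoris", "gastrocnemius_medialis",
           "soleus", "tibialis_anterior"]


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study-condition parameters for one synthetic trial."""

    condition: str = "assisted"         # {assisted, unassisted}
    cycle_duration: float = 2.0         # s per gait cycle
    n_cycles: int = 2
    speed: float = 0.47                 # m/s forward progression
    amplitudes: dict = field(default_factory=dict)  # deg overrides
    marker_noise_sd: float = 0.005      # m
    occlusion_rate: float = 0.02
    marker_rate: float = 100.0          # Hz
    analog_rate: float = 2000.0         # Hz
    stance_fraction: float = 0.6
    double_support: float = 0.1         # cycle fraction of weight transfer
    encoder_offset_deg: float = 12.0    # constant frame offset vs skeleton
    encoder_noise_sd_deg: float = 1.0
    encoder_rate: float = 200.0
    emg_resting_offset: float = 0.02
    seed: int = 0

    @classmethod
    def for_condition(cls, condition: str, seed: int = 0,
                      **overrides) -> "SynthConfig":
        if condition == "assisted":
            cfg = cls(condition="assisted", cycle_duration=2.0, speed=0.47,
                      seed=seed)
        elif condition == "unassisted":
            cfg = cls(condition="unassisted", cycle_duration=1.1, speed=1.11,
                      seed=seed)
        else:
            raise SynthError(f"unknown condition {condition!r}")
        return replace(cfg, **overrides)

    @classmethod
    def standing(cls, seed: int = 0, duration: float = 3.0) -> "SynthConfig":
        """Static quiet-standing trial (zero amplitudes, zero speed)."""
        cfg = cls(condition="unassisted", cycle_duration=duration, n_cycles=1,
                  speed=0.0, seed=seed)
        cfg.amplitudes = {"__static__": 1.0}
        return cfg

    @property
    def is_static(self) -> bool:
        return "__static__" in self.amplitudes


# joint waveform defaults per condition: peak knee flexion, peak hip
# flexion/extension, ankle amplitude + phase (all deg, flexion positive)
_CONDITION_WAVES = {
    "assisted": {"knee_peak": 50.1, "hip_flex_peak": 35.0,
                 "hip_ext_peak": 3.1, "ankle_amp": 6.9, "ankle_phase": 0.0,
                 "arm_swing": 3.0, "elbow_offset": 25.0},
    "unassisted": {"knee_peak": 68.6, "hip_flex_peak": 30.0,
                   "hip_ext_peak": 27.2, "ankle_amp": 15.0,
                   "ankle_phase": 0.3, "arm_swing": 8.0, "elbow_offset": 10.0},
}


@dataclass
class _Wave:
    """offset + rate*t + sum_k a_k cos(2 pi j_k (t/T + s) + phi_k)."""

    offset: float = 0.0
    rate: float = 0.0
    harmonics: list = field(default_factory=list)  # (amp, order, phase rad)
    shift: float = 0.0  # cycle-fraction shift (0.5 for the right side)

    def __call__(self, t, T):
        phase = 2.0 * math.pi * (t / T + self.shift)
        q = self.offset + self.rate * t
        qd = np.full_like(np.asarray(t, float), self.rate)
        qdd = np.zeros_like(qd)
        w = 2.0 * math.pi / T
        for a, j, phi in self.harmonics:
            arg = j * phase + phi
            q = q + a * np.cos(arg)
            qd = qd - a * j * w * np.sin(arg)
            qdd = qdd - a * (j * w) ** 2 * np.cos(arg)
        return q, qd, qdd


def _build_waves(config: SynthConfig, model: MultibodyModel,
                 pelvis_height: float) -> dict[str, _Wave]:
    """Map coordinate names to waveforms for the configured condition."""
    if config.is_static:
        waves = {"pelvis_tz": _Wave(offset=pelvis_height)}
        return waves
    p = dict(_CONDITION_WAVES[config.condition])
    p.update(config.amplitudes)
    hip_mid = 0.5 * (p["hip_flex_peak"] - p["hip_ext_peak"])
    hip_amp = 0.5 * (p["hip_flex_peak"] + p["hip_ext_peak"])
    waves: dict[str, _Wave] = {
        "pelvis_tx": _Wave(rate=config.speed,
                           harmonics=[(0.015, 2, 0.0)]),
        "pelvis_ty": _Wave(harmonics=[(0.01, 1, 0.0)]),
        "pelvis_tz": _Wave(offset=pelvis_height,
                           harmonics=[(0.012, 2, 0.0)]),
        "pelvis_list": _Wave(harmonics=[(1.5 * DEG, 1, 0.0)]),
        "pelvis_tilt": _Wave(offset=2.0 * DEG,
                             harmonics=[(1.0 * DEG, 2, 0.0)]),
        "pelvis_rotation": _Wave(harmonics=[(3.0 * DEG, 1, 0.5)]),
        "back_tilt": _Wave(offset=3.0 * DEG, harmonics=[(1.5 * DEG, 2, 0.0)]),
        "back_list": _Wave(harmonics=[(1.0 * DEG, 1, 0.0)]),
        "back_rotation": _Wave(harmonics=[(2.0 * DEG, 1, 3.14)]),
    }
    for side, s in (("l", 0.0), ("r", 0.5)):
        # knee: zero (extended) at strike, peak flexion mid-swing-ish
        A = p["knee_peak"] * DEG
        waves[f"knee_flexion_{side}"] = _Wave(
            offset=0.5 * A, harmonics=[(-0.5 * A, 1, 0.0)], shift=s)
        waves[f"hip_flexion_{side}"] = _Wave(
            offset=hip_mid * DEG, harmonics=[(hip_amp * DEG, 1, 0.0)],
            shift=s)
        waves[f"hip_adduction_{side}"] = _Wave(
            harmonics=[(2.0 * DEG, 1, 1.0)], shift=s)
        waves[f"hip_rotation_{side}"] = _Wave(
            harmonics=[(2.0 * DEG, 1, 2.0)], shift=s)
        waves[f"ankle_flexion_{side}"] = _Wave(
            harmonics=[(-p["ankle_amp"] * DEG, 1,
                        0.5 * math.pi - 2 * math.pi * p["ankle_phase"])],
            shift=s)
        waves[f"subtalar_inversion_{side}"] = _Wave(
            harmonics=[(2.0 * DEG, 1, 0.7)], shift=s)
        waves[f"mtp_flexion_{side}"] = _Wave(
            offset=3.0 * DEG, harmonics=[(3.0 * DEG, 1, 1.2)], shift=s)
        sw = p["arm_swing"] * DEG
        # arms swing in anti-phase with the ipsilateral leg
        waves[f"shoulder_flexion_{side}"] = _Wave(
            harmonics=[(sw, 1, math.pi)], shift=s)
        waves[f"shoulder_adduction_{side}"] = _Wave(
            harmonics=[(1.0 * DEG, 1, 0.0)], shift=s)
        waves[f"shoulder_rotation_{side}"] = _Wave(
            harmonics=[(1.0 * DEG, 1, 0.6)], shift=s)
        waves[f"elbow_flexion_{side}"] = _Wave(
            offset=p["elbow_offset"] * DEG,
            harmonics=[(2.0 * DEG, 1, math.pi)], shift=s)
        waves[f"pro_sup_{side}"] = _Wave(harmonics=[(1.0 * DEG, 1, 0.0)],
                                         shift=s)
        waves[f"wrist_flexion_{side}"] = _Wave(
            harmonics=[(1.5 * DEG, 1, 0.3)], shift=s)
        waves[f"wrist_deviation_{side}"] = _Wave(
            harmonics=[(1.0 * DEG, 1, 0.9)], shift=s)
        # exoskeleton pins are driven to the same hip/knee angles
        waves[f"exo_hip_flexion_{side}"] = waves[f"hip_flexion_{side}"]
        waves[f"exo_knee_flexion_{side}"] = waves[f"knee_flexion_{side}"]
    # pelvic-band anchor wobble (small relative human-robot motion)
    for cname, amp, j, phi in (("anchor_tx", 0.003, 1, 0.2),
                               ("anchor_ty", 0.003, 1, 1.1),
                               ("anchor_tz", 0.004, 2, 0.5),
                               ("anchor_rx", 0.8 * DEG, 1, 0.0),
                               ("anchor_ry", 0.8 * DEG, 1, 0.7),
                               ("anchor_rz", 0.5 * DEG, 1, 1.9)):
        waves[cname] = _Wave(harmonics=[(amp, j, phi)])
    return waves


def _standing_pelvis_height(model: MultibodyModel) -> float:
    """Pelvis vertical coordinate that puts the lowest marker 1 cm above
    ground at the neutral pose."""
    fk = forward_kinematics(model, model.neutral_pose())
    zmin = float(fk.markers[:, 2].min()) if model.n_markers else -0.95
    return 0.01 - zmin


def generate_gait_trajectory(config: SynthConfig,
                             model: MultibodyModel) -> CoordinateTrajectory:
    """Smooth periodic coordinate trajectories with analytic derivatives.

    Left and right legs run half a cycle out of phase; the pelvis translates
    forward at the configured speed.  Coordinates without a waveform stay at
    zero.  Amplitudes beyond +/- pi/2 on rotational joints are rejected.
    """
    T = config.cycle_duration
    t = np.arange(0.0, config.n_cycles * T, 1.0 / config.marker_rate)
    waves = _build_waves(config, model, _standing_pelvis_height(model))
    Q = np.zeros((t.size, model.n_coordinates))
    Qd = np.zeros_like(Q)
    Qdd = np.zeros_like(Q)
    kinds = model.coordinate_kinds()
    for ci, name in enumerate(model.coordinate_names):
        wave = waves.get(name)
        if wave is None:
            continue
        q, qd, qdd = wave(t, T)
        if kinds[ci] == "rotation":
            amp = np.max(np.abs(q))
            if amp > 0.5 * math.pi + 1e-9 and not name.startswith("pelvis"):
                raise SynthError(f"{name}: amplitude {amp / DEG:.1f} deg out "
                                 "of joint range")
        Q[:, ci], Qd[:, ci], Qdd[:, ci] = q, qd, qdd
    return CoordinateTrajectory(time=t, q=Q, qdot=Qd, qddot=Qdd,
                                coordinate_names=list(model.coordinate_names))


def generate_markers(model: MultibodyModel, traj: CoordinateTrajectory,
                     noise_sd: float = 0.005, occlusion_rate: float = 0.0,
                     seed: int | np.random.Generator = 0
                     ) -> MarkerTrajectorySet:
    """Forward-kinematics marker clouds + i.i.d. Gaussian noise + random
    occlusion gaps, on the marker clock."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    T = traj.n_frames
    P = np.zeros((T, model.n_markers, 3))
    for k in range(T):
        P[k] = forward_kinematics(model, traj.q[k]).markers
    if noise_sd > 0:
        P = P + rng.normal(0.0, noise_sd, size=P.shape)
    occ = rng.random((T, model.n_markers)) < occlusion_rate
    markers = {}
    occluded = {}
    for m, name in enumerate(model.marker_names):
        markers[name] = P[:, m].copy()
        occluded[name] = occ[:, m].copy()
    return MarkerTrajectorySet(time=traj.time.copy(), markers=markers,
                               occluded=occluded)


def _stance_weight(phi: np.ndarray, stance_fraction: float,
                   ramp: float) -> np.ndarray:
    phi = np.mod(phi, 1.0)
    w = np.zeros_like(phi)
    mid = (phi >= ramp) & (phi <= stance_fraction - ramp)
    w[mid] = 1.0
    up = phi < ramp
    w[up] = 0.5 * (1.0 - np.cos(np.pi * phi[up] / ramp))
    down = (phi > stance_fraction - ramp) & (phi <= stance_fraction)
    w[down] = 0.5 * (1.0 - np.cos(np.pi * (stance_fraction - phi[down]) / ramp))
    return w


def generate_consistent_loads(model: MultibodyModel,
                              traj: CoordinateTrajectory,
                              config: SynthConfig | None = None,
                              left_body: str = "calcn_l",
                              right_body: str = "calcn_r"
                              ) -> list[ExternalLoad]:
    """Foot loads satisfying whole-body Newton-Euler exactly, per frame.

    The required resultant wrench (sum of m_i (a_i - g) and the matching
    moment) is split between the feet by the stance-weight blend (equal split
    for static trials); each foot's share is applied at a COP on the ground
    under that foot, with a free moment closing the balance.  A frame where
    neither foot bears weight (flight) is rejected.
    """
    if traj.qddot is None:
        raise SynthError("trajectory must carry exact accelerations")
    g = GRAVITY
    masses = np.array([s.mass for s in model.segments.values()])
    inertias = np.array([s.inertia for s in model.segments.values()])
    T = traj.n_frames
    F_req = np.zeros((T, 3))
    M_req = np.zeros((T, 3))
    foot_pos = {left_body: np.zeros((T, 3)), right_body: np.zeros((T, 3))}
    for k in range(T):
        bk = body_kinematics(model, traj.q[k], traj.qdot[k], traj.qddot[k])
        fk = bk.fk
        F_req[k] = masses @ bk.a_com - masses.sum() * g
        Iw = np.einsum("sij,sjk,slk->sil", fk.R, inertias, fk.R)
        Hdot = (np.einsum("sij,sj->si", Iw, bk.alpha)
                + np.cross(bk.omega, np.einsum("sij,sj->si", Iw, bk.omega))
                + np.cross(bk.com, masses[:, None] * bk.a_com))
        M_req[k] = Hdot.sum(axis=0) - np.cross(
            bk.com, masses[:, None] * g[None, :]).sum(axis=0)
        for body in (left_body, right_body):
            foot_pos[body][k] = fk.p[model.segment_index[body]]
    if config is not None and not config.is_static:
        phi = traj.time / config.cycle_duration
        wl = _stance_weight(phi, config.stance_fraction, config.double_support)
        wr = _stance_weight(phi + 0.5, config.stance_fraction,
                            config.double_support)
        tot = wl + wr
        if np.any(tot < 1e-9):
            raise SynthError("flight phase encountered; not modeled")
        wl, wr = wl / tot, wr / tot
    else:
        wl = np.full(T, 0.5)
        wr = np.full(T, 0.5)
    loads = []
    for body, w in ((left_body, wl), (right_body, wr)):
        force = w[:, None] * F_req
        cop = foot_pos[body].copy()
        cop[:, 2] = 0.0
        moment_gap = M_req - (np.cross(foot_pos[left_body] * [1, 1, 0],
                                       wl[:, None] * F_req)
                              + np.cross(foot_pos[right_body] * [1, 1, 0],
                                         wr[:, None] * F_req))
        free = w[:, None] * moment_gap
        loads.append(ExternalLoad(body=body, time=traj.time.copy(),
                                  force=force, cop=cop, free_moment=free))
    return loads


# ---------------------------------------------------------------------------
# EMG and encoder emulation
# ---------------------------------------------------------------------------

# burst centers/widths in cycle fraction, base amplitudes (arbitrary units);
# the plantarflexors fire in propulsion, tibialis anterior around strike
_BURSTS = {
    "rectus_femoris": [(0.05, 0.25, 0.6), (0.95, 0.15, 0.4)],
    "vastus_lateralis": [(0.07, 0.25, 0.8)],
    "vastus_medialis": [(0.07, 0.25, 0.7)],
    "semitendinosus": [(0.92, 0.25, 0.7)],
    "biceps_femoris": [(0.92, 0.25, 0.6)],
    "gastrocnemius_medialis": [(0.45, 0.3, 0.9)],
    "soleus": [(0.45, 0.3, 0.8)],
    "tibialis_anterior": [(0.0, 0.2, 0.7), (0.7, 0.3, 0.4)],
}
# assisted walking attenuates braking/propulsion musculature
_ASSISTED_SCALE = {"gastrocnemius_medialis": 0.35, "soleus": 0.35,
                   "tibialis_anterior": 0.4}


def _burst_envelope(phi, bursts):
    env = np.zeros_like(phi)
    for c, w, a in bursts:
        d = np.mod(phi - c + 0.5, 1.0) - 0.5
        m = np.abs(d) < 0.5 * w
        env[m] += a * 0.5 * (1.0 + np.cos(2.0 * np.pi * d[m] / w))
    return env


def _emg_carrier(n, fs, rng):
    from .signals import butterworth_filter
    x = rng.normal(size=n)
    x = butterworth_filter(x, "highpass", 50.0, fs=fs, zero_phase=False)
    x = butterworth_filter(x, "lowpass", 450.0, fs=fs, zero_phase=False)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms


def generate_emg(config: SynthConfig,
                 seed: int | np.random.Generator | None = None) -> dict:
    """16-channel burst-modulated EMG plus MVC trials with known maxima.

    Channels are ``<muscle>_<side>``; bursts are phase-locked to each leg's
    gait cycle.  Returns ``{"time", "channels", "mvc_trials",
    "resting_offset", "fs"}``; MVC trials are five isometric recordings per
    muscle whose envelope peak exceeds the gait-trial activation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(config.seed if seed is None else seed)
    fs = config.analog_rate
    T = config.n_cycles * config.cycle_duration
    t = np.arange(0.0, T, 1.0 / fs)
    channels = {}
    for side, shift in (("l", 0.0), ("r", 0.5)):
        phi = np.mod(t / config.cycle_duration + shift, 1.0)
        for muscle in MUSCLES:
            scale = 1.0
            if config.condition == "assisted":
                scale = _ASSISTED_SCALE.get(muscle, 0.8)
            env = 0.02 + scale * _burst_envelope(phi, _BURSTS[muscle]) \
                if not config.is_static else np.full_like(phi, 0.0)
            carrier = _emg_carrier(t.size, fs, rng)
            channels[f"{muscle}_{side}"] = (env * carrier
                                            + config.emg_resting_offset)
    mvc_trials = {}
    t_mvc = np.arange(0.0, 3.0, 1.0 / fs)
    ramps = [0.6, 0.85, 1.0, 0.9, 0.7]
    for side in ("l", "r"):
        for muscle in MUSCLES:
            recs = []
            for frac in ramps:
                env = 1.2 * frac * _burst_envelope(
                    np.clip(t_mvc / 3.0, 0, 1), [(0.5, 0.8, 1.0)])
                carrier = _emg_carrier(t_mvc.size, fs, rng)
                recs.append(env * carrier + config.emg_resting_offset)
            mvc_trials[f"{muscle}_{side}"] = recs
    return {"time": t, "channels": channels, "mvc_trials": mvc_trials,
            "mvc_time": t_mvc, "resting_offset": config.emg_resting_offset,
            "fs": fs}


def generate_encoder(traj: CoordinateTrajectory, config: SynthConfig,
                     joints: list[str] | None = None,
                     seed: int | np.random.Generator | None = None,
                     activation_times: list[float] | None = None) -> dict:
    """Exoskeleton motor-encoder streams: joint angle + constant frame offset
    + Gaussian noise (degrees), with motor-activation timestamps."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(config.seed if seed is None else seed)
    if joints is None:
        joints = [c for c in (traj.coordinate_names or [])
                  if c.startswith("exo_")]
    if not joints:
        raise SynthError("trajectory has no exoskeleton joint coordinates")
    t = np.arange(traj.time[0], traj.time[-1] + 1e-12,
                  1.0 / config.encoder_rate)
    channels = {}
    for name in joints:
        q_deg = np.interp(t, traj.time, traj.column(name)) / DEG
        noise = rng.normal(0.0, config.encoder_noise_sd_deg, size=t.size)
        channels[name] = q_deg + config.encoder_offset_deg + noise
    return {"time": t, "channels": channels,
            "offset_deg": config.encoder_offset_deg,
            "activation_times": list(activation_times or [])}


# ---------------------------------------------------------------------------
# full labeled trial bundles
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthBundle:
    """One synthetic trial with every stream and its generating truth."""

    condition: str
    config: SynthConfig
    traj: CoordinateTrajectory          # IK-model coordinates, exact derivs
    id_traj: CoordinateTrajectory       # restriction to the dynamics model
    markers: MarkerTrajectorySet
    loads: list[ExternalLoad]
    torques: object                     # GeneralizedForces ground truth
    emg: dict
    encoder: dict | None
    events: dict                        # foot -> {"strikes": [...], "toeoffs": [...]}


@dataclass
class ConditionModels:
    """The models one condition's pipeline runs on."""

    ik_model: MultibodyModel   # tracks markers (coupled for assisted)
    id_model: MultibodyModel   # carries inertia (lumped for assisted)
    human: MultibodyModel
    exo: MultibodyModel | None
    exo_mass: float


def build_condition_models(condition: str,
                           anthro: SubjectAnthropometry | None = None
                           ) -> ConditionModels:
    """Scaled human (+ coupled/lumped exoskeleton for assisted trials)."""
    human = scale_model(build_human_model(), anthro or default_subject())
    if condition == "assisted":
        exo = build_exoskeleton_model()
        coupled = couple_models(human, exo)
        lumped = lump_exoskeleton_inertia(human, exo)
        return ConditionModels(ik_model=coupled, id_model=lumped,
                               human=human, exo=exo,
                               exo_mass=exo.total_mass)
    return ConditionModels(ik_model=human, id_model=human, human=human,
                           exo=None, exo_mass=0.0)


def _restrict(traj: CoordinateTrajectory,
              model: MultibodyModel) -> CoordinateTrajectory:
    idx = [traj.coordinate_names.index(c) for c in model.coordinate_names]
    return CoordinateTrajectory(
        time=traj.time, q=traj.q[:, idx],
        qdot=None if traj.qdot is None else traj.qdot[:, idx],
        qddot=None if traj.qddot is None else traj.qddot[:, idx],
        coordinate_names=list(model.coordinate_names))


def _truth_events(config: SynthConfig) -> dict:
    T = config.cycle_duration
    total = config.n_cycles * T
    out = {}
    for foot, shift in (("left", 0.0), ("right", 0.5)):
        strikes = [k * T + shift * T for k in range(-1, config.n_cycles + 1)]
        strikes = [s for s in strikes if 0.0 <= s <= total]
        toeoffs = [s + config.stance_fraction * T for s in
                   [k * T + shift * T for k in range(-1, config.n_cycles + 1)]]
        toeoffs = [s for s in toeoffs if 0.0 <= s <= total]
        out[foot] = {"strikes": strikes, "toeoffs": toeoffs}
    return out


def generate_trial(config: SynthConfig,
                   models: ConditionModels | None = None
                   ) -> GroundTruthBundle:
    """Generate one fully labeled trial for the configured condition."""
    if models is None:
        models = build_condition_models(config.condition)
    rng = np.random.default_rng(config.seed)
    traj = generate_gait_trajectory(config, models.ik_model)
    id_traj = (_restrict(traj, models.id_model)
               if models.ik_model is not models.id_model else traj)
    markers = generate_markers(models.ik_model, traj,
                               noise_sd=config.marker_noise_sd,
                               occlusion_rate=config.occlusion_rate, seed=rng)
    loads = generate_consistent_loads(models.id_model, id_traj, config)
    torques = inverse_dynamics(models.id_model, id_traj, loads)
    emg = generate_emg(config, seed=rng)
    encoder = None
    if models.exo is not None:
        encoder = generate_encoder(traj, config, seed=rng)
    return GroundTruthBundle(condition=config.condition, config=config,
                             traj=traj, id_traj=id_traj, markers=markers,
                             loads=loads, torques=torques, emg=emg,
                             encoder=encoder, events=_truth_events(config))


def generate_trials(condition: str, n_trials: int = 6, seed: int = 0,
                    models: ConditionModels | None = None,
                    **config_overrides) -> list[GroundTruthBundle]:
    """Six successful trials per condition by default, seeds derived from
    ``seed`` so the set is reproducible."""
    if models is None:
        models = build_condition_models(condition)
    out = []
    for k in range(n_trials):
        cfg = SynthConfig.for_condition(condition,
                                        seed=(seed * 1000 + k) % (2 ** 31 - 1),
                                        **config_overrides)
        out.append(generate_trial(cfg, models))
    return out
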