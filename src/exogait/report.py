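"""Condition-level summary tables from processed trials.

Mirrors the study's reporting: per-leg, per-condition mean +/- SD (over
trials) of peak joint angles, peak normalized joint moments, and peak
normalized ground reaction forces in the braking and propulsion phases, plus
the ankle range in propulsion.  Peaks are extrema of per-trial curves within
gait-cycle windows (cut from each foot's vertical GRF); means of per-trial
peaks, never peaks of mean curves.  Flexion/dorsiflexion are positive
internally; extension/plantarflexion peaks are reported as positive
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import GeneralizedForces
from .events import detect_gait_events, split_braking_propulsion
from .kinematics import CoordinateTrajectory, differentiate_trajectory
from .signals import normalize_grf

DEG = np.pi / 180.0


@dataclass
class TrialData:
    """Processed streams of one trial, on the marker clock."""

    traj: CoordinateTrajectory          # IK output
    loads: list                         # ExternalLoad per foot
    moments: GeneralizedForces | None = None


def _per_cycle_peaks(time, series, cycles, window="cycle"):
    peaks = []
    for c in cycles:
        if window == "cycle":
            t0, t1 = c.t_strike, c.t_next_strike
        elif window == "stance":
            t0, t1 = c.t_strike, c.t_toeoff
        sel = (time >= t0) & (time <= t1)
        if sel.any():
            peaks.append(series[sel])
    return peaks


def _load_for(loads, body):
    for ld in loads:
        if ld.body == body:
            return ld
    raise KeyError(body)


def trial_measures(trial: TrialData, condition: str, subject_mass: float,
                   exo_mass: float, smooth_hz: float = 6.0,
                   threshold: float = 20.0) -> list[dict]:
    """Per-trial peak measures for both legs (one dict per quantity)."""
    traj = trial.traj
    if smooth_hz is not None:
        traj = differentiate_trajectory(traj, smooth_hz=smooth_hz)
        traj = CoordinateTrajectory(time=traj.time, q=traj.q,
                                    coordinate_names=trial.traj.coordinate_names)
    out = []
    for side, leg, body in (("l", "left", "calcn_l"), ("r", "right",
                                                       "calcn_r")):
        ld = _load_for(trial.loads, body)
        cycles = detect_gait_events(ld.time, ld.force[:, 2],
                                    threshold=threshold, foot=leg)
        if not cycles:
            continue
        knee = traj.column(f"knee_flexion_{side}") / DEG
        hip = traj.column(f"hip_flexion_{side}") / DEG
        ankle = traj.column(f"ankle_flexion_{side}") / DEG

        def peak(series, direction, window="cycle"):
            segs = _per_cycle_peaks(traj.time, series, cycles, window)
            if not segs:
                return np.nan
            vals = [s.max() if direction == "max" else s.min() for s in segs]
            return float(np.mean(vals))

        out.append({"quantity": "peak_knee_flexion_deg", "leg": leg,
                    "value": peak(knee, "max")})
        out.append({"quantity": "peak_hip_extension_deg", "leg": leg,
                    "value": -peak(hip, "min")})
        out.append({"quantity": "peak_ankle_plantarflexion_deg", "leg": leg,
                    "value": -peak(ankle, "min")})
        # propulsion-phase ankle range (braking/propulsion split on AP shear)
        ranges = []
        grf_rows = {k: [] for k in ("vgrf_braking", "vgrf_propulsion",
                                    "posterior", "anterior")}
        fbw = normalize_grf(ld.force, condition, subject_mass, exo_mass)
        for c in cycles:
            split = split_braking_propulsion(ld.time, ld.force[:, 0],
                                             c.stance)
            if split.propulsion is not None:
                t0, t1 = split.propulsion
                sel = (traj.time >= t0) & (traj.time <= t1)
                if sel.any():
                    ranges.append(ankle[sel].max() - ankle[sel].min())
                gsel = (ld.time >= t0) & (ld.time <= t1)
                if gsel.any():
                    grf_rows["vgrf_propulsion"].append(fbw[gsel, 2].max())
                    grf_rows["anterior"].append(fbw[gsel, 0].max())
            if split.braking is not None:
                t0, t1 = split.braking
                gsel = (ld.time >= t0) & (ld.time <= t1)
                if gsel.any():
                    grf_rows["vgrf_braking"].append(fbw[gsel, 2].max())
                    grf_rows["posterior"].append(-fbw[gsel, 0].min())
        if ranges:
            out.append({"quantity": "ankle_propulsion_range_deg", "leg": leg,
                        "value": float(np.mean(ranges))})
        for key, name in (("vgrf_braking", "peak_vertical_grf_braking_bw"),
                          ("vgrf_propulsion",
                           "peak_vertical_grf_propulsion_bw"),
                          ("posterior", "peak_posterior_grf_braking_bw"),
                          ("anterior", "peak_anterior_grf_propulsion_bw")):
            if grf_rows[key]:
                out.append({"quantity": name, "leg": leg,
                            "value": float(np.mean(grf_rows[key]))})
        if trial.moments is not None:
            mass = subject_mass + exo_mass if condition == "assisted" \
                else subject_mass
            for cname, qname, sign in (
                    (f"knee_flexion_{side}",
                     "peak_knee_extension_moment_nm_per_kg", -1.0),
                    (f"hip_flexion_{side}",
                     "peak_hip_flexion_moment_nm_per_kg", 1.0),
                    (f"ankle_flexion_{side}",
                     "peak_ankle_plantarflexion_moment_nm_per_kg", -1.0)):
                m = sign * trial.moments.column(cname) / mass
                segs = _per_cycle_peaks(trial.moments.time, m, cycles,
                                        "stance")
                if segs:
                    out.append({"quantity": qname, "leg": leg,
                                "value": float(np.mean([s.max()
                                                        for s in segs]))})
    return out


def condition_report(trials: list[TrialData], condition: str,
                     subject_mass: float, exo_mass: float,
                     **opts) -> pd.DataFrame:
    """Mean +/- SD over trials of every per-trial peak measure."""
    rows = []
    for k, trial in enumerate(trials):
        for rec in trial_measures(trial, condition, subject_mass, exo_mass,
                                  **opts):
            rows.append({**rec, "trial": k})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["condition", "quantity", "leg",
                                     "n_trials", "mean", "sd"])
    grouped = df.groupby(["quantity", "leg"])["value"]
    out = grouped.agg(n_trials="count", mean="mean",
                      sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
    out = out.reset_index()
    out.insert(0, "condition", condition)
    return out.sort_values(["quantity", "leg"]).reset_index(drop=True)
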