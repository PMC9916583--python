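"""Trial segmentation and ensemble statistics.

Gait cycles are cut from the filtered vertical ground reaction force of each
foot: foot strike is an upward crossing of a force threshold (20 N default),
toe-off the matching downward crossing, with a 50 ms debounce against
threshold-grazing noise.  Stance splits into braking and propulsion at the
last posterior-to-anterior zero crossing of the anterior-posterior shear.
Curves are time-normalized to a 101-point 0-100% cycle grid and aggregated as
mean +/- sample SD over trials; peak summaries are the mean +/- SD of
per-trial extrema (never the extremum of the mean curve).

Powered sit-to-stand / stand-to-sit maneuvers follow the device protocol:
a positioning phase (torso pitched into the commanded lean), a ~3 s hold, then
motor activation driving the rise or descent; phase boundaries come from the
motor-activation timestamp when available, else from torso-pitch plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class EventError(ValueError):
    pass


@dataclass
class GaitCycle:
    foot: str
    t_strike: float
    t_toeoff: float
    t_next_strike: float

    def __post_init__(self):
        if not (self.t_strike < self.t_toeoff < self.t_next_strike):
            raise EventError("gait cycle events out of order")

    @property
    def stance(self) -> tuple[float, float]:
        return (self.t_strike, self.t_toeoff)


@dataclass
class ManeuverPhases:
    maneuver: str
    t_position_end: float
    t_hold_end: float
    t_complete: float

    def __post_init__(self):
        if not (self.t_position_end <= self.t_hold_end <= self.t_complete):
            raise EventError("maneuver phases out of order")


@dataclass
class EnsembleCurve:
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_trials: int
    leg: str = ""
    condition: str = ""


@dataclass
class PeakSummary:
    quantity: str
    phase: str
    mean: float
    sd: float
    peaks: np.ndarray
    leg: str = ""
    condition: str = ""
    direction: str = "max"


def _threshold_crossings(time, x, threshold, debounce):
    above = x >= threshold
    idx = np.flatnonzero(np.diff(above.astype(int)))
    events = []  # (t, +1 up / -1 down)
    last_t = -np.inf
    for i in idx:
        direction = 1 if above[i + 1] else -1
        t = time[i + 1]
        if t - last_t < debounce:
            # grazing: cancel the bounce pair
            if events and events[-1][1] == -direction:
                events.pop()
                last_t = events[-1][0] if events else -np.inf
            continue
        events.append((t, direction))
        last_t = t
    return events


def detect_gait_events(time: np.ndarray, vertical_force: np.ndarray,
                       threshold: float = 20.0, debounce: float = 0.050,
                       foot: str = "left") -> list[GaitCycle]:
    """Foot strikes and toe-offs from one foot's vertical GRF.

    Strike = upward crossing of ``threshold`` (N), toe-off = downward
    crossing; crossings closer than ``debounce`` seconds are treated as
    threshold-grazing noise and merged.  Returns complete strike -> toe-off ->
    next-strike cycles.
    """
    time = np.asarray(time, float)
    x = np.asarray(vertical_force, float)
    events = _threshold_crossings(time, x, threshold, debounce)
    if not events:
        raise EventError("no events: force never crosses the threshold")
    strikes = [t for t, d in events if d > 0]
    toeoffs = [t for t, d in events if d < 0]
    cycles = []
    for k, ts in enumerate(strikes[:-1]):
        tn = strikes[k + 1]
        offs = [t for t in toeoffs if ts < t < tn]
        if offs:
            cycles.append(GaitCycle(foot=foot, t_strike=ts, t_toeoff=offs[0],
                                    t_next_strike=tn))
    if not cycles and strikes:
        # partial cycle: stance without a following strike
        offs = [t for t in toeoffs if t > strikes[0]]
        if offs:
            cycles.append(GaitCycle(foot=foot, t_strike=strikes[0],
                                    t_toeoff=offs[0],
                                    t_next_strike=float("inf")))
    return cycles


@dataclass
class StanceSplit:
    boundary: float | None
    braking: tuple[float, float] | None
    propulsion: tuple[float, float] | None
    label: str = ""  # dominant sign label when no crossing exists


def split_braking_propulsion(time: np.ndarray, ap_force: np.ndarray,
                             stance: tuple[float, float]) -> StanceSplit:
    """Split stance at the last posterior->anterior zero crossing of the AP
    shear force (posterior negative).  With no sign change the whole stance is
    labeled by the dominant sign and a warning is issued."""
    time = np.asarray(time, float)
    ap = np.asarray(ap_force, float)
    t0, t1 = stance
    sel = (time >= t0) & (time <= t1)
    if not sel.any():
        raise EventError("stance window outside the trace")
    t = time[sel]
    x = ap[sel]
    sign = np.sign(x)
    crossings = np.flatnonzero((sign[:-1] < 0) & (sign[1:] >= 0))
    if crossings.size == 0:
        label = "braking" if x.mean() < 0 else "propulsion"
        warnings.warn(f"no braking/propulsion sign change in stance; whole "
                      f"stance labeled {label}")
        if label == "braking":
            return StanceSplit(boundary=None, braking=(t0, t1),
                               propulsion=None, label=label)
        return StanceSplit(boundary=None, braking=None, propulsion=(t0, t1),
                           label=label)
    i = crossings[-1]
    # linear interpolation of the zero time
    x0, x1 = x[i], x[i + 1]
    tb = t[i] if x1 == x0 else t[i] + (t[i + 1] - t[i]) * (-x0) / (x1 - x0)
    return StanceSplit(boundary=float(tb), braking=(t0, float(tb)),
                       propulsion=(float(tb), t1))


def detect_maneuver_phases(maneuver: str, time: np.ndarray | None = None,
                           torso_pitch: np.ndarray | None = None,
                           activation_time: float | None = None,
                           plateau_tol: float = 0.5,
                           min_plateau: float = 1.0) -> ManeuverPhases:
    """Positioning / hold / rise-or-descend boundaries for powered maneuvers.

    Prefers the exoskeleton's motor-activation timestamp for the end of the
    hold; otherwise (and for the remaining boundaries) detects plateaus of the
    torso pitch: positioning ends when the pitch settles within
    ``plateau_tol`` degrees of the hold plateau, completion is the onset of
    the final plateau.
    """
    if maneuver not in ("sit_to_stand", "stand_to_sit"):
        raise EventError(f"unknown maneuver {maneuver!r}")
    if torso_pitch is None:
        if activation_time is None:
            raise EventError("need torso pitch or an activation timestamp")
        # degenerate: timestamps only
        return ManeuverPhases(maneuver=maneuver,
                              t_position_end=activation_time - 3.0,
                              t_hold_end=activation_time,
                              t_complete=activation_time)
    time = np.asarray(time, float)
    pitch = np.asarray(torso_pitch, float)
    dt = time[1] - time[0]
    win = max(3, int(round(min_plateau / dt)))
    # plateau mask: local range below tolerance
    flat = np.zeros(time.size, dtype=bool)
    for i in range(time.size - win):
        seg = pitch[i:i + win]
        if seg.max() - seg.min() < plateau_tol:
            flat[i] = True
    runs = _runs(flat)
    # drop the initial resting plateau (starts at the first sample)
    runs = [r for r in runs if r[0] > 0]
    if not runs:
        raise EventError("no torso-pitch plateau detected")
    hold = runs[0]
    t_position_end = float(time[hold[0]])
    if activation_time is not None:
        t_hold_end = float(activation_time)
    else:
        t_hold_end = float(time[hold[1] - 1] + min_plateau)
    final_runs = [r for r in runs if time[r[0]] > t_hold_end]
    if final_runs:
        t_complete = float(time[final_runs[-1][0]])
    else:
        t_complete = float(time[-1])
    t_complete = max(t_complete, t_hold_end)
    return ManeuverPhases(maneuver=maneuver, t_position_end=t_position_end,
                          t_hold_end=t_hold_end, t_complete=t_complete)


def _runs(mask):
    """Contiguous True runs as (start, stop) index pairs."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def time_normalize(time: np.ndarray, values: np.ndarray,
                   window: tuple[float, float],
                   n_points: int = 101) -> np.ndarray:
    """Resample a series onto a uniform 0-100% grid over ``window``."""
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    t0, t1 = window
    if not (t1 > t0):
        raise EventError("degenerate normalization window")
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9:
        raise EventError("window outside series support")
    grid = np.linspace(t0, t1, n_points)
    if values.ndim == 1:
        return np.interp(grid, time, values)
    return np.column_stack([np.interp(grid, time, values[:, k])
                            for k in range(values.shape[1])])


def ensemble_average(trials: list[np.ndarray], leg: str = "",
                     condition: str = "") -> EnsembleCurve:
    """Pointwise mean and sample SD (n-1) over time-normalized trials."""
    if not trials:
        raise EventError("no trials to average")
    arr = np.asarray(trials, float)
    n = arr.shape[0]
    if n == 1:
        warnings.warn("ensemble of a single trial: SD reported as 0")
        sd = np.zeros(arr.shape[1:])
    else:
        sd = arr.std(axis=0, ddof=1)
    grid = np.linspace(0.0, 100.0, arr.shape[1])
    return EnsembleCurve(grid=grid, mean=arr.mean(axis=0), sd=sd,
                         n_trials=n, leg=leg, condition=condition)


def peak_summary(trials: list[tuple[np.ndarray, np.ndarray]],
                 quantity: str, phase: str = "cycle",
                 windows: list[tuple[float, float]] | None = None,
                 direction: str = "max", leg: str = "",
                 condition: str = "") -> PeakSummary:
    """Mean +/- SD of per-trial extrema within a phase window.

    ``trials`` is a list of (time, values) pairs; ``windows`` gives the phase
    window per trial (default: the full series).
    """
    if not trials:
        raise EventError("no trials")
    if direction not in ("max", "min"):
        raise EventError("direction must be max or min")
    peaks = []
    for k, (time, values) in enumerate(trials):
        time = np.asarray(time, float)
        values = np.asarray(values, float)
        if windows is not None:
            t0, t1 = windows[k]
            sel = (time >= t0) & (time <= t1)
            if not sel.any():
                raise EventError(f"trial {k}: empty phase window")
            values = values[sel]
        peaks.append(values.max() if direction == "max" else values.min())
    peaks = np.asarray(peaks, float)
    sd = float(peaks.std(ddof=1)) if peaks.size > 1 else 0.0
    return PeakSummary(quantity=quantity, phase=phase,
                       mean=float(peaks.mean()), sd=sd, peaks=peaks,
                       leg=leg, condition=condition, direction=direction)
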