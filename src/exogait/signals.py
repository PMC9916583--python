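"""Ground-reaction-force and EMG conditioning chains.

GRF chain: low-pass fourth-order Butterworth at 15 Hz on the force
components, optional decimation to the marker clock, and normalization to
body weight (unassisted) or combined body + device weight (assisted).

EMG chain, in exactly this order: subtract the resting mean (from quiet
standing), fourth-order 30 Hz high-pass to remove motion artifact, full-wave
rectification, fourth-order 6 Hz Butterworth low-pass (the linear envelope),
and division by the muscle's maximum voluntary contraction (MVC) value — the
peak of the envelope over the five MVC trials.

All offline filters are zero-phase by default (forward-backward passes, which
double the effective attenuation order); pass ``zero_phase=False`` for a
single causal pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt


class SignalError(ValueError):
    pass


@dataclass
class AnalogTrace:
    """A uniformly sampled analog channel (scalar or vector-valued)."""

    time: np.ndarray
    values: np.ndarray
    units: str
    name: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.values = np.asarray(self.values, float)
        if not self.units:
            raise SignalError("units must be declared")
        if self.time.size != self.values.shape[0]:
            raise SignalError("time and values length mismatch")
        if self.time.size > 1:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise SignalError("sampling is not uniform (jitter > 1 ns)")

    @property
    def fs(self) -> float:
        if self.time.size < 2:
            raise SignalError("cannot infer sampling rate from < 2 samples")
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class GRFRecord:
    """One force plate's force / COP / free-moment streams."""

    time: np.ndarray
    force: np.ndarray
    cop: np.ndarray
    free_moment: np.ndarray
    plate: str = "plate1"
    normalized: bool = False
    normalizing_weight: float | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        for name in ("force", "cop", "free_moment"):
            arr = np.asarray(getattr(self, name), float)
            setattr(self, name, arr)
            if arr.shape != (self.time.size, 3):
                raise SignalError(f"{name} must be (T, 3)")

    @property
    def fs(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


MVCTable = dict  # muscle name -> maximum activation (raw EMG units)


def _apply_sos(x: np.ndarray, sos, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sosfiltfilt(sos, x, axis=0)
    return sosfilt(sos, x, axis=0)


def butterworth_filter(values: np.ndarray | AnalogTrace, kind: str,
                       cutoff: float, fs: float | None = None,
                       order: int = 4, zero_phase: bool = True):
    """Fourth-order (per pass) Butterworth low- or high-pass filter.

    Accepts a raw array (``fs`` required) or an :class:`AnalogTrace`.
    Zero-phase filtering runs forward and backward, squaring the magnitude
    response (so the -3 dB point of a single pass becomes -6 dB).
    """
    if kind not in ("lowpass", "highpass"):
        raise SignalError(f"kind must be lowpass/highpass, got {kind!r}")
    if isinstance(values, AnalogTrace):
        out = _apply_sos(values.values,
                         _design(kind, cutoff, values.fs, order), zero_phase)
        return replace(values, values=out)
    if fs is None:
        raise SignalError("fs is required for array input")
    return _apply_sos(np.asarray(values, float),
                      _design(kind, cutoff, fs, order), zero_phase)


def _design(kind, cutoff, fs, order):
    if cutoff >= fs / 2:
        raise SignalError(
            f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    return butter(order, cutoff, btype="low" if kind == "lowpass" else "high",
                  fs=fs, output="sos")


def process_grf(raw: GRFRecord, cutoff: float = 15.0, order: int = 4,
                zero_phase: bool = True,
                resample_to: float | None = None) -> GRFRecord:
    """Low-pass the force components (15 Hz default); optionally resample
    all streams to a lower clock (e.g. 100 Hz) for alignment with marker
    data."""
    sos = _design("lowpass", cutoff, raw.fs, order)
    force = _apply_sos(raw.force, sos, zero_phase)
    moment = _apply_sos(raw.free_moment, sos, zero_phase)
    time, cop = raw.time, raw.cop
    if resample_to is not None:
        new_t = np.arange(raw.time[0], raw.time[-1] + 0.5 / resample_to,
                          1.0 / resample_to)
        new_t = new_t[new_t <= raw.time[-1] + 1e-12]
        force = np.column_stack([np.interp(new_t, raw.time, force[:, k])
                                 for k in range(3)])
        moment = np.column_stack([np.interp(new_t, raw.time, moment[:, k])
                                  for k in range(3)])
        cop = np.column_stack([np.interp(new_t, raw.time, raw.cop[:, k])
                               for k in range(3)])
        time = new_t
    return GRFRecord(time=time, force=force, cop=cop, free_moment=moment,
                     plate=raw.plate, normalized=raw.normalized,
                     normalizing_weight=raw.normalizing_weight)


def normalize_grf(force: np.ndarray, condition: str, subject_mass: float,
                  exo_mass: float = 0.0, g: float = 9.81) -> np.ndarray:
    """Express forces in body-weight units.

    Assisted locomotion normalizes to the combined weight of participant and
    exoskeleton; unassisted to the participant's body weight.
    """
    if condition not in ("assisted", "unassisted"):
        raise SignalError(f"unknown condition {condition!r}")
    if subject_mass <= 0 or exo_mass < 0:
        raise SignalError("masses must be positive")
    mass = subject_mass + exo_mass if condition == "assisted" else subject_mass
    return np.asarray(force, float) / (mass * g)


def denormalize_grf(force_bw: np.ndarray, condition: str, subject_mass: float,
                    exo_mass: float = 0.0, g: float = 9.81) -> np.ndarray:
    mass = subject_mass + exo_mass if condition == "assisted" else subject_mass
    return np.asarray(force_bw, float) * (mass * g)


def compute_resting_mean(trace: np.ndarray | AnalogTrace) -> float:
    """Mean raw EMG during quiet standing (the zero-offset reference)."""
    values = trace.values if isinstance(trace, AnalogTrace) else \
        np.asarray(trace, float)
    if values.size == 0:
        raise SignalError("empty resting trial")
    return float(values.mean())


def emg_envelope(raw: np.ndarray, fs: float, resting_mean: float = 0.0,
                 highpass_hz: float = 30.0, lowpass_hz: float = 6.0,
                 order: int = 4, zero_phase: bool = True) -> np.ndarray:
    """Linear envelope: offset removal -> 30 Hz HP -> |.| -> 6 Hz LP."""
    x = np.asarray(raw, float) - resting_mean
    x = _apply_sos(x, _design("highpass", highpass_hz, fs, order), zero_phase)
    x = np.abs(x)
    return _apply_sos(x, _design("lowpass", lowpass_hz, fs, order), zero_phase)


def process_emg(raw: np.ndarray | AnalogTrace, resting_mean: float,
                mvc: float, fs: float | None = None,
                **env_opts) -> np.ndarray:
    """Full EMG chain ending in MVC normalization (unitless, ~0-1)."""
    if mvc <= 0:
        raise SignalError("mvc must be positive")
    if isinstance(raw, AnalogTrace):
        fs = raw.fs
        raw = raw.values
    if fs is None:
        raise SignalError("fs is required for array input")
    return emg_envelope(raw, fs, resting_mean=resting_mean, **env_opts) / mvc


def compute_mvc(trials: dict[str, list], fs: float | None = None,
                resting_mean: float = 0.0, **env_opts) -> MVCTable:
    """Maximum voluntary contraction per muscle.

    ``trials`` maps muscle name to its (nominally five) isometric-contraction
    recordings; the muscle's maximum activation is the peak of the rectified
    envelope over all trials.
    """
    table: MVCTable = {}
    for muscle, recs in trials.items():
        if not recs:
            raise SignalError(f"{muscle}: empty MVC trial set")
        peak = -np.inf
        for rec in recs:
            if isinstance(rec, AnalogTrace):
                env = emg_envelope(rec.values, rec.fs,
                                   resting_mean=resting_mean, **env_opts)
            else:
                if fs is None:
                    raise SignalError("fs is required for array trials")
                env = emg_envelope(np.asarray(rec, float), fs,
                                   resting_mean=resting_mean, **env_opts)
            peak = max(peak, float(env.max()))
        if peak <= 0:
            raise SignalError(f"{muscle}: nonpositive MVC")
        table[muscle] = peak
    return table
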