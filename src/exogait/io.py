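"""Readers and writers for motion-capture text formats.

TRC (marker trajectories), MOT/STO (coordinates, loads, moments), CSV (EMG
and encoder streams), JSON (events, ground truth), and YAML (model and
anthropometry configs).  Values are converted to SI on read (TRC mm -> m,
``inDegrees=yes`` -> rad for rotational columns); floats are written with 8
significant digits, which our readers round-trip bit-identically.  The
internal world frame is Z-up; a Y-up lab convention can be applied at the
TRC boundary with ``up="y"``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ExternalLoad, GeneralizedForces
from .kinematics import CoordinateTrajectory, MarkerTrajectorySet
from .model import MultibodyModel, SubjectAnthropometry

DEG = np.pi / 180.0
FLOAT_FMT = "%.8g"


class FileFormatError(ValueError):
    pass


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(mset: MarkerTrajectorySet, path, units: str = "mm",
              up: str = "z") -> None:
    path = Path(path)
    names = list(mset.markers)
    rate = 1.0 / (mset.time[1] - mset.time[0]) if mset.n_frames > 1 else 100.0
    scale = {"mm": 1000.0, "m": 1.0}.get(units)
    if scale is None:
        raise FileFormatError(f"unknown TRC units {units!r}")
    T = mset.n_frames
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{_fmt(rate)}\t{_fmt(rate)}\t{T}\t{len(names)}\t{units}\t"
        f"{_fmt(rate)}\t1\t{T}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}"
                           for i in range(len(names))),
    ]
    for k in range(T):
        row = [str(k + 1), _fmt(mset.time[k])]
        for name in names:
            if mset.occluded[name][k] or not np.all(
                    np.isfinite(mset.markers[name][k])):
                row += ["", "", ""]
            else:
                x, y, z = mset.markers[name][k] * scale
                if up == "y":
                    x, y, z = x, z, -y
                row += [_fmt(x), _fmt(y), _fmt(z)]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path, up: str = "z") -> MarkerTrajectorySet:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise FileFormatError(f"{path}: truncated TRC file")
    header = lines[2].split("\t")
    try:
        n_frames = int(header[2])
        n_markers = int(header[3])
        units = header[4]
    except (IndexError, ValueError) as exc:
        raise FileFormatError(f"{path}: malformed TRC header") from exc
    scale = {"mm": 1e-3, "m": 1.0}.get(units)
    if scale is None:
        raise FileFormatError(f"{path}: unknown units {units!r}")
    names = [n for n in lines[3].split("\t")[2:] if n.strip()]
    if len(names) != n_markers:
        raise FileFormatError(
            f"{path}: header declares {n_markers} markers, found {len(names)}")
    rows = [ln for ln in lines[5:] if ln.strip()]
    if len(rows) != n_frames:
        raise FileFormatError(
            f"{path}: header declares {n_frames} frames, found {len(rows)}")
    time = np.zeros(n_frames)
    data = np.full((n_frames, n_markers, 3), np.nan)
    for k, ln in enumerate(rows):
        cells = ln.split("\t")
        if len(cells) < 2 + 3 * n_markers:
            cells += [""] * (2 + 3 * n_markers - len(cells))
        time[k] = float(cells[1])
        for m in range(n_markers):
            trio = cells[2 + 3 * m: 5 + 3 * m]
            if all(c.strip() for c in trio):
                x, y, z = (float(c) * scale for c in trio)
                if up == "y":
                    x, y, z = x, -z, y
                data[k, m] = (x, y, z)
    markers = {name: data[:, m] for m, name in enumerate(names)}
    occluded = {name: np.any(~np.isfinite(data[:, m]), axis=1)
                for m, name in enumerate(names)}
    return MarkerTrajectorySet(time=time, markers=markers, occluded=occluded)


# ---------------------------------------------------------------------------
# MOT / STO
# ---------------------------------------------------------------------------

def write_mot(df: pd.DataFrame, path, in_degrees: bool = False,
              name: str | None = None) -> None:
    path = Path(path)
    cols = list(df.columns)
    lines = [
        name or path.stem,
        "version=1",
        f"nRows={len(df)}",
        f"nColumns={len(cols)}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
        "\t".join(cols),
    ]
    for _, row in df.iterrows():
        lines.append("\t".join(_fmt(v) for v in row.to_numpy()))
    path.write_text("\n".join(lines) + "\n")


def read_mot(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    lines = path.read_text().splitlines()
    meta = {"in_degrees": False, "name": None}
    n_rows = n_cols = None
    body_start = None
    for i, ln in enumerate(lines):
        low = ln.strip().lower()
        if i == 0:
            meta["name"] = ln.strip()
        if low.startswith("nrows"):
            n_rows = int(ln.split("=")[1])
        elif low.startswith("ncolumns"):
            n_cols = int(ln.split("=")[1])
        elif low.startswith("indegrees"):
            meta["in_degrees"] = ln.split("=")[1].strip().lower() == "yes"
        elif low == "endheader":
            body_start = i + 1
            break
    if body_start is None:
        raise FileFormatError(f"{path}: missing endheader")
    cols = lines[body_start].split("\t")
    if n_cols is not None and len(cols) != n_cols:
        raise FileFormatError(
            f"{path}:{body_start + 1}: nColumns={n_cols} but header row has "
            f"{len(cols)} columns")
    rows = []
    for j, ln in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not ln.strip():
            continue
        cells = ln.split("\t")
        if len(cells) != len(cols):
            raise FileFormatError(
                f"{path}:{j}: expected {len(cols)} columns, found {len(cells)}")
        rows.append([float(c) for c in cells])
    if n_rows is not None and len(rows) != n_rows:
        raise FileFormatError(
            f"{path}: nRows={n_rows} but found {len(rows)} data rows "
            "(truncated file?)")
    df = pd.DataFrame(rows, columns=cols)
    time = df["time"].to_numpy()
    if time.size > 1 and np.any(np.diff(time) <= 0):
        raise FileFormatError(f"{path}: time column not strictly increasing")
    return df, meta


def trajectory_to_mot(traj: CoordinateTrajectory, model: MultibodyModel,
                      path, in_degrees: bool = True) -> None:
    kinds = model.coordinate_kinds()
    data = {"time": traj.time}
    for ci, cname in enumerate(model.coordinate_names):
        col = traj.q[:, ci]
        if in_degrees and kinds[ci] == "rotation":
            col = col / DEG
        data[cname] = col
    write_mot(pd.DataFrame(data), path, in_degrees=in_degrees)


def mot_to_trajectory(path, model: MultibodyModel) -> CoordinateTrajectory:
    df, meta = read_mot(path)
    kinds = model.coordinate_kinds()
    q = np.zeros((len(df), model.n_coordinates))
    for ci, cname in enumerate(model.coordinate_names):
        if cname not in df.columns:
            raise FileFormatError(f"{path}: missing coordinate {cname}")
        col = df[cname].to_numpy()
        if meta["in_degrees"] and kinds[ci] == "rotation":
            col = col * DEG
        q[:, ci] = col
    return CoordinateTrajectory(time=df["time"].to_numpy(), q=q,
                                coordinate_names=list(model.coordinate_names))


def write_loads_sto(loads: list[ExternalLoad], path) -> None:
    data = {"time": loads[0].time}
    for ld in loads:
        for tag, arr in (("force_v", ld.force), ("force_p", ld.cop),
                         ("torque_", ld.free_moment)):
            for k, ax in enumerate("xyz"):
                data[f"{ld.body}_{tag}{ax}"] = arr[:, k]
    write_mot(pd.DataFrame(data), path, in_degrees=False, name="loads")


def read_loads_sto(path) -> list[ExternalLoad]:
    df, _ = read_mot(path)
    bodies = sorted({c[: -len("_force_vx")] for c in df.columns
                     if c.endswith("_force_vx")})
    if not bodies:
        raise FileFormatError(f"{path}: no *_force_vx columns")
    time = df["time"].to_numpy()
    loads = []
    for body in bodies:
        get = lambda tag: np.column_stack(  # noqa: E731
            [df[f"{body}_{tag}{ax}"].to_numpy() for ax in "xyz"])
        loads.append(ExternalLoad(body=body, time=time, force=get("force_v"),
                                  cop=get("force_p"),
                                  free_moment=get("torque_")))
    return loads


def write_forces_sto(gf: GeneralizedForces, model: MultibodyModel,
                     path) -> None:
    kinds = model.coordinate_kinds()
    data = {"time": gf.time}
    for ci, cname in enumerate(gf.coordinate_names):
        suffix = "_moment" if kinds[ci] == "rotation" else "_force"
        data[f"{cname}{suffix}"] = gf.tau[:, ci]
    write_mot(pd.DataFrame(data), path, in_degrees=False, name="moments")


def read_forces_sto(path, model: MultibodyModel) -> GeneralizedForces:
    df, _ = read_mot(path)
    kinds = model.coordinate_kinds()
    tau = np.zeros((len(df), model.n_coordinates))
    for ci, cname in enumerate(model.coordinate_names):
        suffix = "_moment" if kinds[ci] == "rotation" else "_force"
        tau[:, ci] = df[f"{cname}{suffix}"].to_numpy()
    return GeneralizedForces(time=df["time"].to_numpy(), tau=tau,
                             coordinate_names=list(model.coordinate_names),
                             base_coordinates=list(model.base_coordinates))


# ---------------------------------------------------------------------------
# CSV (EMG, encoder), JSON, YAML
# ---------------------------------------------------------------------------

def write_emg_csv(emg: dict, path) -> None:
    df = pd.DataFrame({"time": emg["time"], **emg["channels"]})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_emg_csv(path) -> dict:
    df = pd.read_csv(path)
    return {"time": df["time"].to_numpy(),
            "channels": {c: df[c].to_numpy() for c in df.columns
                         if c != "time"}}


def write_encoder_csv(encoder: dict, path) -> None:
    path = Path(path)
    header = "# activation_times: " + ",".join(
        _fmt(t) for t in encoder.get("activation_times", [])) + "\n"
    df = pd.DataFrame({"time": encoder["time"], **encoder["channels"]})
    path.write_text(header + df.to_csv(index=False, float_format=FLOAT_FMT))


def read_encoder_csv(path) -> dict:
    path = Path(path)
    text = path.read_text().splitlines()
    activation = []
    if text and text[0].startswith("# activation_times:"):
        payload = text[0].split(":", 1)[1].strip()
        activation = [float(x) for x in payload.split(",") if x]
    df = pd.read_csv(path, comment="#")
    return {"time": df["time"].to_numpy(),
            "channels": {c: df[c].to_numpy() for c in df.columns
                         if c != "time"},
            "activation_times": activation}


def write_events_json(cycles_by_foot: dict, path) -> None:
    out = {}
    for foot, cycles in cycles_by_foot.items():
        out[foot] = [{"t_strike": c.t_strike, "t_toeoff": c.t_toeoff,
                      "t_next_strike": c.t_next_strike} for c in cycles]
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True) + "\n")


def read_events_json(path) -> dict:
    from .events import GaitCycle
    raw = json.loads(Path(path).read_text())
    return {foot: [GaitCycle(foot=foot, **c) for c in cycles]
            for foot, cycles in raw.items()}


def save_model_config(model: MultibodyModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_config(),
                                         sort_keys=False))


def load_model_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def load_anthropometry(path) -> SubjectAnthropometry:
    raw = yaml.safe_load(Path(path).read_text())
    return SubjectAnthropometry(
        total_mass=float(raw["total_mass"]), height=float(raw["height"]),
        segment_lengths={k: float(v)
                         for k, v in (raw.get("segment_lengths") or {}).items()})


def save_anthropometry(anthro: SubjectAnthropometry, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "total_mass": anthro.total_mass, "height": anthro.height,
        "segment_lengths": anthro.segment_lengths}, sort_keys=False))
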