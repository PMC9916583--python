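"""Human and exoskeleton multibody models.

A model is a tree of rigid inertial segments connected by typed joints.  One
joint attaches its tree to the world frame (parent ``"ground"``).  Each joint
compiles to a short chain of primitive transforms (fixed, revolute, prismatic,
coordinate-coupled translation); the kinematics and dynamics modules operate on
that compiled chain, so every joint type is handled uniformly.

The default human model has 24 segments and 37 generalized coordinates
(6 ground-pelvis, 3 torso, 7 per leg, 7 per arm); the default powered
exoskeleton has 7 segments and 4 coordinates (left/right hip and knee pins,
welded ankles).  Generic geometry, mass fractions, and marker offsets are
editable approximations shipped in :func:`default_human_config` — they stand in
for the anthropometric tables of standard generic gait models, which are not
reproduced here.

Internal conventions: SI units, Z-up world frame, gravity along -Z,
flexion/dorsiflexion positive.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._transforms import is_spd, normalized, rotation_about_axis

GROUND = "ground"

#: generalized-coordinate count per joint type
JOINT_DOFS = {
    "pin": 1,
    "ball": 3,
    "universal2": 2,
    "universal6": 6,
    "weld": 0,
    "coupled_knee": 1,
}


class ModelError(ValueError):
    """Raised for invalid model definitions (topology, names, inertia...)."""


@dataclass
class MarkerAttachment:
    name: str
    segment: str
    local_position: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        self.local_position = np.asarray(self.local_position, dtype=float)
        if self.weight < 0:
            raise ModelError(f"marker {self.name}: negative weight")


@dataclass
class InertialSegment:
    name: str
    mass: float
    com: np.ndarray
    inertia: np.ndarray
    length: float | None = None
    attached_markers: list[MarkerAttachment] = field(default_factory=list)

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.inertia.shape == (3,):
            self.inertia = np.diag(self.inertia)
        if self.mass < 0:
            raise ModelError(f"segment {self.name}: negative mass")
        if not is_spd(self.inertia):
            raise ModelError(f"segment {self.name}: inertia not symmetric PSD")


@dataclass
class JointSpec:
    """A typed joint between ``parent`` and ``child`` segments.

    ``parent_offset``/``parent_rotation`` place the joint frame on the parent
    segment; ``child_offset``/``child_rotation`` place it on the child (the
    child frame origin coincides with the joint frame when both are zero).
    ``axes`` lists the successive motion axes (unit vectors in the joint
    frame): 1 for pin/coupled_knee, 2 for universal2, 3 rotation axes for ball
    and universal6 (whose three translations always precede the rotations and
    run along the joint-frame x/y/z).
    """

    name: str
    type: str
    parent: str
    child: str
    parent_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    child_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    parent_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    child_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    axes: np.ndarray | None = None
    coordinates: list[str] | None = None
    coupling_table: dict | None = None

    def __post_init__(self):
        if self.type not in JOINT_DOFS:
            raise ModelError(f"joint {self.name}: unknown type {self.type!r}")
        self.parent_offset = np.asarray(self.parent_offset, dtype=float)
        self.child_offset = np.asarray(self.child_offset, dtype=float)
        self.parent_rotation = np.asarray(self.parent_rotation, dtype=float)
        self.child_rotation = np.asarray(self.child_rotation, dtype=float)
        n_rot = {"pin": 1, "coupled_knee": 1, "universal2": 2, "ball": 3,
                 "universal6": 3, "weld": 0}[self.type]
        if self.axes is None:
            defaults = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0],
                                 [0.0, 0.0, 1.0]])
            self.axes = defaults[:n_rot].copy()
        else:
            self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        if self.type != "weld" and self.axes.shape != (n_rot, 3):
            raise ModelError(
                f"joint {self.name}: expected {n_rot} axes, got {self.axes.shape}")
        if self.type != "weld":
            self.axes = np.array([normalized(a, f"joint {self.name} axis")
                                  for a in self.axes])
        if self.coordinates is None:
            self.coordinates = [f"{self.name}_q{i}" for i in range(self.dofs)]
        if len(self.coordinates) != self.dofs:
            raise ModelError(
                f"joint {self.name}: {len(self.coordinates)} coordinate names "
                f"for {self.dofs} DoFs")

    @property
    def dofs(self) -> int:
        return JOINT_DOFS[self.type]


@dataclass
class SubjectAnthropometry:
    total_mass: float
    height: float
    segment_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.total_mass > 0:
            raise ModelError("total_mass must be positive")
        if not self.height > 0:
            raise ModelError("height must be positive")
        for seg, L in self.segment_lengths.items():
            if not L > 0:
                raise ModelError(f"segment length {seg} must be positive")


def _coupling_splines(table: dict):
    """Build (f, df, d2f) translation splines from a coupling table.

    Table maps joint angle (rad) to prescribed child-frame translation (m):
    ``{"angle": [...], "translation": [[tx,ty,tz], ...]}``.
    """
    ang = np.asarray(table["angle"], dtype=float)
    tr = np.asarray(table["translation"], dtype=float)
    if tr.shape != (ang.size, 3):
        raise ModelError("coupling table: translation must be (n, 3)")
    if np.all(tr == 0.0):
        return None
    spl = CubicSpline(ang, tr, axis=0)
    d1 = spl.derivative(1)
    d2 = spl.derivative(2)
    return spl, d1, d2


class MultibodyModel:
    """A kinematic tree of inertial segments with attached markers."""

    def __init__(self, segments: list[InertialSegment], joints: list[JointSpec],
                 name: str = "model", meta: dict | None = None):
        self.name = name
        self.meta = dict(meta or {})
        self.segments: dict[str, InertialSegment] = {}
        for seg in segments:
            if seg.name in self.segments or seg.name == GROUND:
                raise ModelError(f"duplicated segment name {seg.name!r}")
            self.segments[seg.name] = seg
        self.joints = list(joints)
        self._validate_tree()
        self._compile()

    # -- structure ---------------------------------------------------------
    def _validate_tree(self):
        child_joint: dict[str, JointSpec] = {}
        for j in self.joints:
            if j.child not in self.segments:
                raise ModelError(f"joint {j.name}: unknown child {j.child!r}")
            if j.parent != GROUND and j.parent not in self.segments:
                raise ModelError(f"joint {j.name}: unknown parent {j.parent!r}")
            if j.child in child_joint:
                raise ModelError(
                    f"non-tree topology: segment {j.child!r} has two parent joints")
            child_joint[j.child] = j
        missing = set(self.segments) - set(child_joint)
        if missing:
            raise ModelError(f"segments with no parent joint: {sorted(missing)}")
        roots = [j for j in self.joints if j.parent == GROUND]
        if len(roots) != 1:
            raise ModelError(
                f"expected exactly one ground joint, found {len(roots)}")
        # reachability from ground => no cycles (tree with |joints|==|segments|)
        order, seen = [], {GROUND}
        frontier = [GROUND]
        while frontier:
            nxt = []
            for j in self.joints:
                if j.parent in seen and j.child not in seen:
                    seen.add(j.child)
                    order.append(j)
                    nxt.append(j.child)
            if not nxt:
                break
            frontier = nxt
        if len(order) != len(self.joints):
            raise ModelError("non-tree topology: joint graph contains a cycle "
                             "or disconnected component")
        self._joint_order = order
        self.child_joint = child_joint
        self.root = roots[0].child

    def _compile(self):
        # coordinate layout in topological joint order
        self.coordinate_names: list[str] = []
        self.coordinate_layout: list[tuple[str, int, str]] = []
        coord_index: dict[str, int] = {}
        for j in self._joint_order:
            kinds = (["translation"] * 3 + ["rotation"] * 3
                     if j.type == "universal6"
                     else ["rotation"] * j.dofs)
            for i, cname in enumerate(j.coordinates):
                if cname in coord_index:
                    raise ModelError(f"duplicated coordinate name {cname!r}")
                coord_index[cname] = len(self.coordinate_names)
                self.coordinate_names.append(cname)
                self.coordinate_layout.append((j.name, i, kinds[i]))
        self.coordinate_index = coord_index
        self.n_coordinates = len(self.coordinate_names)
        self.n_segments = len(self.segments)
        declared = self.meta.get("expected_coordinates")
        if declared is not None and declared != self.n_coordinates:
            raise ModelError(
                f"DoF count mismatch: model has {self.n_coordinates} "
                f"coordinates, declared layout expects {declared}")
        declared = self.meta.get("expected_segments")
        if declared is not None and declared != self.n_segments:
            raise ModelError(
                f"segment count mismatch: {self.n_segments} vs declared {declared}")

        self.segment_names = list(self.segments)
        self.segment_index = {n: i for i, n in enumerate(self.segment_names)}
        self.base_joint = self._joint_order[0]
        self.base_coordinates = [coord_index[c] for c in self.base_joint.coordinates]

        # primitive chains per joint
        self._chains = []
        for j in self._joint_order:
            prims = [("fixed", j.parent_rotation, j.parent_offset)]
            ci0 = coord_index[j.coordinates[0]] if j.dofs else None
            if j.type == "universal6":
                for k, ax in enumerate(np.eye(3)):
                    prims.append(("trans", ax, ci0 + k))
                for k, ax in enumerate(j.axes):
                    prims.append(("rev", ax, ci0 + 3 + k))
            elif j.type in ("pin", "ball", "universal2"):
                for k, ax in enumerate(j.axes):
                    prims.append(("rev", ax, ci0 + k))
            elif j.type == "coupled_knee":
                prims.append(("rev", j.axes[0], ci0))
                if j.coupling_table is not None:
                    spl = _coupling_splines(j.coupling_table)
                    if spl is not None:
                        prims.append(("ctrans", *spl, ci0))
            elif j.type == "weld":
                pass
            inv_r = j.child_rotation.T
            prims.append(("fixed", inv_r, -inv_r @ j.child_offset))
            self._chains.append((j, self.segment_index[j.child],
                                 None if j.parent == GROUND
                                 else self.segment_index[j.parent], prims))

        # subtree (descendant-or-self segment) mask per coordinate
        children = {}
        for j in self.joints:
            children.setdefault(j.parent, []).append(j.child)
        self._subtree_of_segment: dict[str, np.ndarray] = {}
        for seg in self.segment_names:
            mask = np.zeros(self.n_segments, dtype=bool)
            stack = [seg]
            while stack:
                s = stack.pop()
                mask[self.segment_index[s]] = True
                stack.extend(children.get(s, []))
            self._subtree_of_segment[seg] = mask
        self.coord_subtree = np.zeros((self.n_coordinates, self.n_segments),
                                      dtype=bool)
        for j in self._joint_order:
            for cname in j.coordinates:
                self.coord_subtree[coord_index[cname]] = \
                    self._subtree_of_segment[j.child]

        # marker tables
        self.marker_names: list[str] = []
        self.marker_segment: list[int] = []
        locs, wts = [], []
        for seg in self.segments.values():
            for mk in seg.attached_markers:
                if mk.name in self.marker_names:
                    raise ModelError(f"duplicated marker name {mk.name!r}")
                self.marker_names.append(mk.name)
                self.marker_segment.append(self.segment_index[seg.name])
                locs.append(mk.local_position)
                wts.append(mk.weight)
        self.marker_segment = np.asarray(self.marker_segment, dtype=int)
        self.marker_locals = (np.asarray(locs, dtype=float)
                              if locs else np.zeros((0, 3)))
        self.marker_weights = np.asarray(wts, dtype=float)
        self.n_markers = len(self.marker_names)
        self.coord_marker_mask = self.coord_subtree[:, self.marker_segment] \
            if self.n_markers else np.zeros((self.n_coordinates, 0), dtype=bool)

    # -- convenience -------------------------------------------------------
    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments.values()))

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def coordinate_kinds(self) -> list[str]:
        return [kind for _, _, kind in self.coordinate_layout]

    def neutral_pose(self) -> np.ndarray:
        return np.zeros(self.n_coordinates)

    def copy(self) -> "MultibodyModel":
        return MultibodyModel(
            [_copy.deepcopy(s) for s in self.segments.values()],
            [_copy.deepcopy(j) for j in self.joints],
            name=self.name, meta=dict(self.meta))

    # -- (de)serialization -------------------------------------------------
    def to_config(self) -> dict:
        segs = []
        for s in self.segments.values():
            segs.append({
                "name": s.name, "mass": float(s.mass),
                "com": [float(x) for x in s.com],
                "inertia": [[float(x) for x in row] for row in s.inertia],
                "length": None if s.length is None else float(s.length),
                "markers": [{"name": m.name,
                             "position": [float(x) for x in m.local_position],
                             "weight": float(m.weight)}
                            for m in s.attached_markers],
            })
        joints = []
        for j in self.joints:
            joints.append({
                "name": j.name, "type": j.type,
                "parent": j.parent, "child": j.child,
                "parent_offset": [float(x) for x in j.parent_offset],
                "child_offset": [float(x) for x in j.child_offset],
                "parent_rotation": [[float(x) for x in r] for r in j.parent_rotation],
                "child_rotation": [[float(x) for x in r] for r in j.child_rotation],
                "axes": [[float(x) for x in a] for a in j.axes],
                "coordinates": list(j.coordinates),
                "coupling_table": j.coupling_table,
            })
        return {"name": self.name, "meta": dict(self.meta),
                "segments": segs, "joints": joints}

    @classmethod
    def from_config(cls, config: dict) -> "MultibodyModel":
        return build_model(config)


def build_model(config: dict) -> MultibodyModel:
    """Build a :class:`MultibodyModel` from a model-definition config dict."""
    segments = []
    for s in config["segments"]:
        markers = [MarkerAttachment(m["name"], s["name"],
                                    m["position"], m.get("weight", 1.0))
                   for m in s.get("markers", [])]
        segments.append(InertialSegment(
            name=s["name"], mass=float(s["mass"]), com=s["com"],
            inertia=np.asarray(s["inertia"], dtype=float),
            length=s.get("length"), attached_markers=markers))
    joints = []
    for j in config["joints"]:
        joints.append(JointSpec(
            name=j["name"], type=j["type"], parent=j["parent"],
            child=j["child"],
            parent_offset=j.get("parent_offset", np.zeros(3)),
            child_offset=j.get("child_offset", np.zeros(3)),
            parent_rotation=j.get("parent_rotation", np.eye(3)),
            child_rotation=j.get("child_rotation", np.eye(3)),
            axes=j.get("axes"), coordinates=j.get("coordinates"),
            coupling_table=j.get("coupling_table")))
    return MultibodyModel(segments, joints, name=config.get("name", "model"),
                          meta=config.get("meta", {}))


# ---------------------------------------------------------------------------
# default generic human model (editable approximation)
# ---------------------------------------------------------------------------

GENERIC_HEIGHT = 1.70
GENERIC_MASS = 75.16

# mass fraction of whole-body mass and gyration radii (fractions of segment
# length, about local x/y/z through the COM); approximate literature values.
_SEG_TABLE = {
    # name: (mass_frac, length, gyration xyz)
    "pelvis":  (0.1117, 0.25, (0.35, 0.30, 0.35)),
    "torso":   (0.3843, 0.50, (0.35, 0.32, 0.20)),
    "clavicle": (0.0040, 0.17, (0.30, 0.10, 0.30)),
    "femur":   (0.1406, 0.40, (0.329, 0.329, 0.149)),
    "patella": (0.0010, 0.04, (0.40, 0.40, 0.40)),
    "tibia":   (0.0433, 0.43, (0.255, 0.249, 0.103)),
    "talus":   (0.0010, 0.05, (0.40, 0.40, 0.40)),
    "calcn":   (0.0100, 0.18, (0.15, 0.25, 0.26)),
    "toes":    (0.0027, 0.07, (0.30, 0.35, 0.35)),
    "humerus": (0.0271, 0.31, (0.285, 0.269, 0.158)),
    "ulna":    (0.0100, 0.26, (0.276, 0.265, 0.121)),
    "radius":  (0.0062, 0.24, (0.276, 0.265, 0.121)),
    "hand":    (0.0061, 0.19, (0.28, 0.25, 0.16)),
}

# flexion-first axis triples (flexion, adduction/inversion, internal rotation);
# flexion/dorsiflexion positive with Z-up, X forward, Y to the subject's left.
_FLEX = [0.0, -1.0, 0.0]
_KNEE_FLEX = [0.0, 1.0, 0.0]


def _seg_entry(base: str, name: str, com, markers, mass_scale=1.0):
    frac, length, gyr = _SEG_TABLE[base]
    mass = frac * GENERIC_MASS * mass_scale
    inertia = [float(mass * (g * length) ** 2) for g in gyr]
    return {"name": name, "mass": mass, "com": list(com),
            "inertia": np.diag(inertia).tolist(), "length": length,
            "markers": markers}


def _mirror(entries, side):
    """Mirror marker/offset y-coordinates for the right side."""
    sgn = 1.0 if side == "l" else -1.0
    out = []
    for name, pos, *rest in entries:
        w = rest[0] if rest else 1.0
        out.append({"name": name, "position": [pos[0], sgn * pos[1], pos[2]],
                    "weight": w})
    return out


def default_human_config() -> dict:
    """Generic 24-segment, 37-DoF whole-body model definition.

    Geometry, mass fractions, and marker offsets approximate a standard
    generic gait model plus a CGM-style marker template; all values are
    editable config, not measured data.
    """
    segs, joints = [], []
    segs.append(_seg_entry("pelvis", "pelvis", (-0.06, 0.0, 0.0), _mirror([
        ("LASI", (0.08, 0.12, 0.01)), ("LPSI", (-0.14, 0.05, 0.02))], "l") +
        _mirror([("RASI", (0.08, 0.12, 0.01)), ("RPSI", (-0.14, 0.05, 0.02))], "r")))
    segs.append(_seg_entry("torso", "torso", (0.0, 0.0, 0.24), [
        {"name": "C7", "position": [-0.07, 0.0, 0.42], "weight": 1.0},
        {"name": "CLAV", "position": [0.06, 0.0, 0.40], "weight": 1.0},
        {"name": "T10", "position": [-0.09, 0.0, 0.20], "weight": 1.0},
        {"name": "STRN", "position": [0.09, 0.0, 0.18], "weight": 1.0}]))
    joints.append({"name": "ground_pelvis", "type": "universal6",
                   "parent": GROUND, "child": "pelvis",
                   "axes": np.eye(3).tolist(),
                   "coordinates": ["pelvis_tx", "pelvis_ty", "pelvis_tz",
                                   "pelvis_list", "pelvis_tilt", "pelvis_rotation"]})
    joints.append({"name": "back", "type": "ball", "parent": "pelvis",
                   "child": "torso", "parent_offset": [0.0, 0.0, 0.10],
                   "axes": [_FLEX, [1, 0, 0], [0, 0, 1]],
                   "coordinates": ["back_tilt", "back_list", "back_rotation"]})
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        S = side.upper()
        segs += [
            _seg_entry("clavicle", f"clavicle_{side}", (0.0, sgn * 0.09, 0.0),
                       _mirror([(f"{S}SHO", (0.0, 0.17, 0.02))], side)),
            _seg_entry("femur", f"femur_{side}", (0.0, 0.0, -0.17), _mirror([
                (f"{S}THI", (0.02, 0.06, -0.16)),
                (f"{S}THI2", (-0.04, 0.05, -0.26)),
                (f"{S}THIA", (0.06, -0.01, -0.12)),
                (f"{S}KNE", (0.0, 0.06, -0.40))], side)),
            _seg_entry("patella", f"patella_{side}", (0.0, 0.0, 0.0), []),
            _seg_entry("tibia", f"tibia_{side}", (0.0, 0.0, -0.19), _mirror([
                (f"{S}TIB", (0.01, 0.055, -0.16)),
                (f"{S}TIB2", (-0.03, 0.045, -0.28)),
                (f"{S}TIBA", (0.05, -0.005, -0.10)),
                (f"{S}ANK", (0.0, 0.055, -0.43))], side)),
            _seg_entry("talus", f"talus_{side}", (0.0, 0.0, -0.02), []),
            _seg_entry("calcn", f"calcn_{side}", (0.08, 0.0, -0.02), _mirror([
                (f"{S}HEE", (-0.05, 0.0, -0.01)),
                (f"{S}HEE2", (-0.06, 0.0, 0.06)),
                (f"{S}MT5", (0.12, 0.045, -0.03)),
                (f"{S}MT1", (0.14, -0.03, -0.03))], side)),
            _seg_entry("toes", f"toes_{side}", (0.03, 0.0, -0.01), _mirror([
                (f"{S}TOE", (0.04, 0.0, -0.02)),
                (f"{S}TOE2", (0.05, 0.03, -0.01))], side)),
            _seg_entry("humerus", f"humerus_{side}", (0.0, 0.0, -0.13), _mirror([
                (f"{S}UPA", (0.0, 0.045, -0.14)),
                (f"{S}UPA2", (0.045, 0.0, -0.20)),
                (f"{S}ELB", (0.0, 0.045, -0.31))], side)),
            _seg_entry("ulna", f"ulna_{side}", (0.0, 0.0, -0.11), _mirror([
                (f"{S}FRM", (-0.02, 0.035, -0.12))], side)),
            _seg_entry("radius", f"radius_{side}", (0.0, 0.0, -0.10), _mirror([
                (f"{S}FRA", (0.035, 0.0, -0.14)),
                (f"{S}WRA", (0.02, 0.03, -0.23)),
                (f"{S}WRB", (-0.02, -0.03, -0.23))], side)),
            _seg_entry("hand", f"hand_{side}", (0.0, 0.0, -0.08), _mirror([
                (f"{S}FIN", (0.01, 0.0, -0.13)),
                (f"{S}FIN2", (0.035, 0.02, -0.06))], side)),
        ]
        joints += [
            {"name": f"clav_{side}", "type": "weld", "parent": "torso",
             "child": f"clavicle_{side}",
             "parent_offset": [0.0, sgn * 0.02, 0.40]},
            {"name": f"hip_{side}", "type": "ball", "parent": "pelvis",
             "child": f"femur_{side}",
             "parent_offset": [0.0, sgn * 0.09, -0.07],
             "axes": [_FLEX, [1, 0, 0], [0, 0, 1]],
             "coordinates": [f"hip_flexion_{side}", f"hip_adduction_{side}",
                             f"hip_rotation_{side}"]},
            {"name": f"knee_{side}", "type": "coupled_knee",
             "parent": f"femur_{side}", "child": f"tibia_{side}",
             "parent_offset": [0.0, 0.0, -0.40], "axes": [_KNEE_FLEX],
             "coordinates": [f"knee_flexion_{side}"],
             "coupling_table": None},
            {"name": f"patellofemoral_{side}", "type": "weld",
             "parent": f"femur_{side}", "child": f"patella_{side}",
             "parent_offset": [0.045, 0.0, -0.38]},
            {"name": f"ankle_{side}", "type": "pin", "parent": f"tibia_{side}",
             "child": f"talus_{side}", "parent_offset": [0.0, 0.0, -0.43],
             "axes": [_FLEX], "coordinates": [f"ankle_flexion_{side}"]},
            {"name": f"subtalar_{side}", "type": "pin",
             "parent": f"talus_{side}", "child": f"calcn_{side}",
             "parent_offset": [0.0, 0.0, -0.04], "axes": [[1.0, 0.0, 0.0]],
             "coordinates": [f"subtalar_inversion_{side}"]},
            {"name": f"mtp_{side}", "type": "pin", "parent": f"calcn_{side}",
             "child": f"toes_{side}", "parent_offset": [0.16, 0.0, -0.02],
             "axes": [_KNEE_FLEX], "coordinates": [f"mtp_flexion_{side}"]},
            {"name": f"shoulder_{side}", "type": "ball",
             "parent": f"clavicle_{side}", "child": f"humerus_{side}",
             "parent_offset": [0.0, sgn * 0.17, 0.0],
             "axes": [_FLEX, [1, 0, 0], [0, 0, 1]],
             "coordinates": [f"shoulder_flexion_{side}",
                             f"shoulder_adduction_{side}",
                             f"shoulder_rotation_{side}"]},
            {"name": f"elbow_{side}", "type": "pin",
             "parent": f"humerus_{side}", "child": f"ulna_{side}",
             "parent_offset": [0.0, 0.0, -0.31], "axes": [_FLEX],
             "coordinates": [f"elbow_flexion_{side}"]},
            {"name": f"radioulnar_{side}", "type": "pin",
             "parent": f"ulna_{side}", "child": f"radius_{side}",
             "parent_offset": [0.01, 0.0, -0.02], "axes": [[0.0, 0.0, 1.0]],
             "coordinates": [f"pro_sup_{side}"]},
            {"name": f"wrist_{side}", "type": "universal2",
             "parent": f"radius_{side}", "child": f"hand_{side}",
             "parent_offset": [0.0, 0.0, -0.24],
             "axes": [_FLEX, [1, 0, 0]],
             "coordinates": [f"wrist_flexion_{side}",
                             f"wrist_deviation_{side}"]},
        ]
    return {"name": "human_generic", "segments": segs, "joints": joints,
            "meta": {"expected_coordinates": 37, "expected_segments": 24,
                     "generic_height": GENERIC_HEIGHT,
                     "generic_mass": GENERIC_MASS}}


# ---------------------------------------------------------------------------
# default exoskeleton model (placeholder inertial set, editable)
# ---------------------------------------------------------------------------

def default_exoskeleton_config(device_mass: float = 23.0) -> dict:
    """Powered lower-limb exoskeleton: 7 segments, 4 DoFs.

    Pin hips and knees, welded ankles, a pelvic band as root.  Segment masses
    are a documented placeholder distribution summing to ``device_mass`` (the
    device's inertial parameters are manufacturer-proprietary and must be
    supplied by the user for quantitative work).
    """
    # fraction of device mass per segment
    fr = {"pelvic_band": 0.390, "thigh": 0.152, "shank": 0.109, "foot": 0.044}

    def seg(name, frac, com, L, gyr, markers):
        m = frac * device_mass
        inertia = np.diag([m * (g * L) ** 2 for g in gyr]).tolist()
        return {"name": name, "mass": m, "com": list(com), "inertia": inertia,
                "length": L, "markers": markers}

    segs = [seg("pelvic_band", fr["pelvic_band"], (-0.05, 0.0, 0.0), 0.30,
                (0.4, 0.35, 0.45), [
                    {"name": "EXO_PB1", "position": [-0.10, 0.15, 0.05], "weight": 1.0},
                    {"name": "EXO_PB2", "position": [-0.10, -0.15, 0.05], "weight": 1.0},
                    {"name": "EXO_PB3", "position": [-0.14, 0.0, -0.03], "weight": 1.0},
                    {"name": "EXO_PB4", "position": [-0.02, 0.0, 0.09], "weight": 1.0}])]
    joints = [{"name": "ground_band", "type": "weld", "parent": GROUND,
               "child": "pelvic_band",
               "parent_offset": [-0.10, 0.0, 0.95]}]
    for side, sgn in (("l", 1.0), ("r", -1.0)):
        S = side.upper()
        segs += [
            seg(f"exo_thigh_{side}", fr["thigh"], (0.0, sgn * 0.02, -0.20),
                0.40, (0.33, 0.33, 0.12), _mirror([
                    (f"EXO_{S}TH1", (0.03, 0.08, -0.10)),
                    (f"EXO_{S}TH2", (-0.03, 0.08, -0.22)),
                    (f"EXO_{S}TH3", (0.04, 0.07, -0.33))], side)),
            seg(f"exo_shank_{side}", fr["shank"], (0.0, sgn * 0.02, -0.18),
                0.43, (0.30, 0.30, 0.12), _mirror([
                    (f"EXO_{S}SH1", (0.03, 0.07, -0.10)),
                    (f"EXO_{S}SH2", (-0.03, 0.07, -0.24)),
                    (f"EXO_{S}SH3", (0.04, 0.06, -0.36))], side)),
            seg(f"exo_foot_{side}", fr["foot"], (0.08, 0.0, -0.03),
                0.25, (0.15, 0.25, 0.26), _mirror([
                    (f"EXO_{S}FT1", (-0.04, 0.04, -0.02)),
                    (f"EXO_{S}FT2", (0.15, 0.04, -0.04))], side)),
        ]
        joints += [
            {"name": f"exo_hip_{side}", "type": "pin", "parent": "pelvic_band",
             "child": f"exo_thigh_{side}",
             "parent_offset": [0.10, sgn * 0.12, -0.07], "axes": [_FLEX],
             "coordinates": [f"exo_hip_flexion_{side}"]},
            {"name": f"exo_knee_{side}", "type": "pin",
             "parent": f"exo_thigh_{side}", "child": f"exo_shank_{side}",
             "parent_offset": [0.0, 0.0, -0.40], "axes": [_KNEE_FLEX],
             "coordinates": [f"exo_knee_flexion_{side}"]},
            {"name": f"exo_ankle_{side}", "type": "weld",
             "parent": f"exo_shank_{side}", "child": f"exo_foot_{side}",
             "parent_offset": [0.0, 0.0, -0.43]},
        ]
    return {"name": "exoskeleton", "segments": segs, "joints": joints,
            "meta": {"expected_coordinates": 4, "expected_segments": 7,
                     "device_mass": device_mass}}


# ---------------------------------------------------------------------------
# build / scale / couple / lump operations
# ---------------------------------------------------------------------------

def build_human_model(config: dict | None = None) -> MultibodyModel:
    """Build the whole-body human model (default: 24 segments, 37 DoFs)."""
    return build_model(default_human_config() if config is None else config)


def build_exoskeleton_model(config: dict | None = None,
                            faithful: bool = True) -> MultibodyModel:
    """Build the exoskeleton model (default: 7 segments, 4 DoFs).

    In ``faithful`` mode the device topology is enforced: hips and knees must
    be pin joints and ankles welds.
    """
    model = build_model(default_exoskeleton_config() if config is None
                        else config)
    if faithful:
        for j in model.joints:
            n = j.name.lower()
            if ("hip" in n or "knee" in n) and j.type != "pin":
                raise ModelError(
                    f"faithful mode: joint {j.name} must be pin, got {j.type}")
            if "ankle" in n and j.type != "weld":
                raise ModelError(
                    f"faithful mode: joint {j.name} must be weld, got {j.type}")
        for s in model.segments.values():
            if s.mass <= 0 and s.name != GROUND:
                raise ModelError(f"faithful mode: segment {s.name} missing mass")
    return model


def default_anchor(human_pelvis: str = "pelvis",
                   exo_root: str = "pelvic_band") -> JointSpec:
    """Six-DoF pelvic-band anchor joining the human pelvis to the device."""
    return JointSpec(
        name="pelvic_anchor", type="universal6",
        parent=human_pelvis, child=exo_root,
        parent_offset=np.array([-0.10, 0.0, 0.0]),
        axes=np.eye(3),
        coordinates=["anchor_tx", "anchor_ty", "anchor_tz",
                     "anchor_rx", "anchor_ry", "anchor_rz"])


def couple_models(human: MultibodyModel, exo: MultibodyModel,
                  anchor: JointSpec | None = None,
                  locked: bool = False) -> MultibodyModel:
    """Join the exoskeleton tree to the human pelvis through the band anchor.

    The anchor must be a six-DoF joint (three translations + three rotations);
    ``locked=True`` welds it instead, removing its six coordinates.
    """
    if anchor is None:
        anchor = default_anchor(human_pelvis=human.root, exo_root=exo.root)
    if locked:
        anchor = JointSpec(name=anchor.name, type="weld", parent=anchor.parent,
                           child=anchor.child,
                           parent_offset=anchor.parent_offset,
                           parent_rotation=anchor.parent_rotation,
                           child_offset=anchor.child_offset,
                           child_rotation=anchor.child_rotation)
    elif anchor.type != "universal6":
        raise ModelError("anchor joint must be universal6 (or use locked=True)")
    if anchor.parent not in human.segments:
        raise ModelError(f"anchor parent {anchor.parent!r} not a human segment")
    if anchor.child != exo.root:
        raise ModelError(f"anchor child {anchor.child!r} is not the "
                         f"exoskeleton root {exo.root!r}")
    dup = set(human.segments) & set(exo.segments)
    if dup:
        raise ModelError(f"duplicate segment names: {sorted(dup)}")
    dup = set(human.marker_names) & set(exo.marker_names)
    if dup:
        raise ModelError(f"duplicate marker names: {sorted(dup)}")
    segs = ([_copy.deepcopy(s) for s in human.segments.values()]
            + [_copy.deepcopy(s) for s in exo.segments.values()])
    joints = [_copy.deepcopy(j) for j in human.joints]
    joints.append(_copy.deepcopy(anchor))
    joints += [_copy.deepcopy(j) for j in exo.joints
               if j.parent != GROUND]
    meta = {"coupled": True}
    return MultibodyModel(segs, joints, name=f"{human.name}+{exo.name}",
                          meta=meta)


def scale_model(model: MultibodyModel,
                anthro: SubjectAnthropometry) -> MultibodyModel:
    """Scale generic geometry and inertia to a subject.

    Per-segment length factors come from ``anthro.segment_lengths`` where
    given, else from the subject/generic height ratio.  Masses keep the
    generic fractions and are rescaled so the total equals
    ``anthro.total_mass``; inertia scales by (mass ratio) x (length ratio)^2.
    Frame offsets and marker positions scale with their segment.
    """
    scaled = model.copy()
    generic_height = model.meta.get("generic_height", GENERIC_HEIGHT)
    global_factor = anthro.height / generic_height
    mass_ratio = anthro.total_mass / model.total_mass
    factors: dict[str, float] = {}
    for seg in scaled.segments.values():
        if seg.name in anthro.segment_lengths:
            if seg.length is None or seg.length <= 0:
                raise ModelError(
                    f"segment {seg.name}: zero/negative generic length")
            factors[seg.name] = anthro.segment_lengths[seg.name] / seg.length
        else:
            factors[seg.name] = global_factor
    for seg in scaled.segments.values():
        s = factors[seg.name]
        seg.com = seg.com * s
        if seg.length is not None:
            seg.length = seg.length * s
        for mk in seg.attached_markers:
            mk.local_position = mk.local_position * s
        seg.inertia = seg.inertia * mass_ratio * s ** 2
        seg.mass = seg.mass * mass_ratio
    for j in scaled.joints:
        if j.parent != GROUND:
            j.parent_offset = j.parent_offset * factors[j.parent]
        j.child_offset = j.child_offset * factors[j.child]
    return MultibodyModel(list(scaled.segments.values()), scaled.joints,
                          name=f"{model.name}_scaled", meta=dict(model.meta))


DEFAULT_LUMP_MAPPING = {
    "pelvic_band": "pelvis",
    "exo_thigh_l": "femur_l", "exo_thigh_r": "femur_r",
    "exo_shank_l": "tibia_l", "exo_shank_r": "tibia_r",
    "exo_foot_l": "calcn_l", "exo_foot_r": "calcn_r",
}


def _parallel_axis(inertia: np.ndarray, mass: float,
                   d: np.ndarray) -> np.ndarray:
    """Transfer an inertia tensor from its COM to a point offset by ``-d``
    (``d`` = COM position minus the new reference point)."""
    return inertia + mass * (float(d @ d) * np.eye(3) - np.outer(d, d))


def lump_exoskeleton_inertia(human: MultibodyModel, exo: MultibodyModel,
                             mapping: dict[str, str] | None = None,
                             anchor: JointSpec | None = None) -> MultibodyModel:
    """Fold the exoskeleton's mass and inertia into the human segments.

    For each mapped pair the combined mass is the sum, the combined COM the
    mass-weighted mean, and the combined tensor the parallel-axis transfer of
    both tensors to the combined COM — all expressed in the human segment
    frame at the coupled models' neutral pose.  The result keeps the human
    topology (same coordinates) so joint moments are reported at the human
    joints.
    """
    from .kinematics import forward_kinematics  # local: avoids import cycle

    if mapping is None:
        mapping = dict(DEFAULT_LUMP_MAPPING)
    missing = set(exo.segments) - set(mapping)
    if missing:
        raise ModelError(f"unmapped exoskeleton segments: {sorted(missing)}")
    unknown = set(mapping.values()) - set(human.segments)
    if unknown:
        raise ModelError(f"mapping targets not in human model: {sorted(unknown)}")

    coupled = couple_models(human, exo, anchor=anchor)
    fk = forward_kinematics(coupled, coupled.neutral_pose())
    lumped = human.copy()
    for exo_name, hum_name in mapping.items():
        e = exo.segments[exo_name]
        h = lumped.segments[hum_name]
        if e.mass == 0.0:
            continue
        Rh = fk.R[coupled.segment_index[hum_name]]
        ph = fk.p[coupled.segment_index[hum_name]]
        Re = fk.R[coupled.segment_index[exo_name]]
        pe = fk.p[coupled.segment_index[exo_name]]
        com_e_h = Rh.T @ (pe + Re @ e.com - ph)
        I_e_h = Rh.T @ (Re @ e.inertia @ Re.T) @ Rh
        m = h.mass + e.mass
        if m <= 0:
            raise ModelError(f"zero combined mass for {hum_name}")
        com = (h.mass * h.com + e.mass * com_e_h) / m
        inertia = (_parallel_axis(h.inertia, h.mass, h.com - com)
                   + _parallel_axis(I_e_h, e.mass, com_e_h - com))
        h.mass, h.com, h.inertia = m, com, inertia
    return MultibodyModel(list(lumped.segments.values()), lumped.joints,
                          name=f"{human.name}_lumped", meta=dict(human.meta))


def default_subject() -> SubjectAnthropometry:
    """Anthropometry of the reference subject (1.76 m, 89.4 kg)."""
    return SubjectAnthropometry(total_mass=89.4, height=1.76)
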