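"""Preset biomechanical structures and model algebra.

Four branched-chain bodies of increasing complexity, labeled a-d:

====== ======= ===== ==========================================================
model  joints  DoF   structure
====== ======= ===== ==========================================================
a      7       7     root L5/S1, shoulders, hips, ankles; every joint a hinge
                     about Y (flexion/extension only); thigh+shank lumped
b      9       13    full legs (hip-knee-ankle); hips and shoulders universal
                     (Y then X), L5/S1/knees/ankles hinges
c      7       17    as (a) but a knee instead of the ankle, and L5/S1,
                     shoulders, hips upgraded to ball-and-socket (Y, X, Z)
d      9       19    as (b) with L5/S1, shoulders and hips ball-and-socket
====== ======= ===== ==========================================================

The prose of such models usually names "L5/S1, shoulders and ankles" for
the simplest body; with 7 segments and two three-deep branches the only
consistent joint set also includes the hips, which is what ships here
(legs hang from hips, feet from ankles).

Multi-DoF rotations follow the ZXY-"fixed" convention of IMU mocap
exports: R = R_y(alpha) R_x(beta) R_z(gamma), applied left to right.
The head is lumped with the trunk; arms are single segments (no elbows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .kinematics import Posture, joint_rotation, rotation_about_axis

__all__ = [
    "JointSpec",
    "KinematicModel",
    "PRESET_IDS",
    "DEFAULT_SKELETON_M",
    "build_preset",
    "count_dof",
    "project_posture",
    "decompose_zxy",
    "model_to_yaml",
    "model_from_yaml",
]

PRESET_IDS = ("a", "b", "c", "d")

#: Neutral adult joint offsets (meters, parent frame) at the finest
#: granularity any preset uses; lumped presets sum across dropped joints.
DEFAULT_SKELETON_M: Dict[str, Tuple[float, float, float]] = {
    "l5s1": (0.0, 0.0, 0.0),
    "shoulder_r": (0.0, -0.18, 0.45),
    "shoulder_l": (0.0, 0.18, 0.45),
    "hip_r": (0.0, -0.09, -0.10),
    "hip_l": (0.0, 0.09, -0.10),
    "knee_r": (0.0, 0.0, -0.44),
    "knee_l": (0.0, 0.0, -0.44),
    "ankle_r": (0.0, 0.0, -0.43),
    "ankle_l": (0.0, 0.0, -0.43),
}

#: Parent of each joint in the full-granularity skeleton.
_SKELETON_PARENT = {
    "l5s1": None,
    "shoulder_r": "l5s1",
    "shoulder_l": "l5s1",
    "hip_r": "l5s1",
    "hip_l": "l5s1",
    "knee_r": "hip_r",
    "knee_l": "hip_l",
    "ankle_r": "knee_r",
    "ankle_l": "knee_l",
}


@dataclass(frozen=True)
class JointSpec:
    """One joint: name, parent (None for the root), constant offset from
    the parent joint expressed in the parent frame (m), and the ordered
    DoF axis sequence ('y',), ('y', 'x') or ('y', 'x', 'z')."""

    name: str
    parent: Optional[str]
    offset: np.ndarray
    dof: Tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if not np.all(np.isfinite(self.offset)):
            raise ValueError(f"joint {self.name!r}: offset must be finite")
        if len(self.dof) == 0 or len(set(self.dof)) != len(self.dof):
            raise ValueError(f"joint {self.name!r}: DoF axes must be non-empty and unique")


@dataclass
class KinematicModel:
    """A rooted tree of joints plus the segment attached distal to each."""

    model_id: str
    joints: List[JointSpec]
    segment_of: Dict[str, str]

    def __post_init__(self):
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            raise ValueError("duplicate joint names")
        roots = [j for j in self.joints if j.parent is None]
        if len(roots) != 1 or self.joints[0].parent is not None:
            raise ValueError("model must have exactly one root joint, listed first")
        known = set()
        for j in self.joints:
            if j.parent is not None and j.parent not in known:
                raise ValueError(
                    f"joint {j.name!r}: parent {j.parent!r} must precede it (tree order)"
                )
            known.add(j.name)
        missing = set(names) - set(self.segment_of)
        if missing:
            raise ValueError(f"joints without an attached segment: {sorted(missing)}")

    @property
    def root(self) -> JointSpec:
        return self.joints[0]

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(name)

    def joint_names(self) -> List[str]:
        return [j.name for j in self.joints]

    def children_of(self, name: str) -> List[JointSpec]:
        return [j for j in self.joints if j.parent == name]

    def path_from_root(self, name: str) -> List[str]:
        """Joint names along the unique root->name path, root first."""
        path = []
        cur: Optional[str] = name
        while cur is not None:
            path.append(cur)
            cur = self.joint(cur).parent
        return path[::-1]


def count_dof(model: KinematicModel) -> int:
    """Total rotational degrees of freedom (sum of DoF sequence lengths)."""
    return sum(len(j.dof) for j in model.joints)


# (joint, parent, dof, segment) tables per preset; offsets resolved from
# the skeleton at build time (lumped joints sum intermediate offsets).
_PRESETS: Dict[str, List[Tuple[str, Optional[str], Tuple[str, ...], str]]] = {
    "a": [
        ("l5s1", None, ("y",), "trunk"),
        ("hip_r", "l5s1", ("y",), "leg_r"),
        ("ankle_r", "hip_r", ("y",), "foot_r"),
        ("hip_l", "l5s1", ("y",), "leg_l"),
        ("ankle_l", "hip_l", ("y",), "foot_l"),
        ("shoulder_r", "l5s1", ("y",), "arm_r"),
        ("shoulder_l", "l5s1", ("y",), "arm_l"),
    ],
    "b": [
        ("l5s1", None, ("y",), "trunk"),
        ("hip_r", "l5s1", ("y", "x"), "thigh_r"),
        ("knee_r", "hip_r", ("y",), "shank_r"),
        ("ankle_r", "knee_r", ("y",), "foot_r"),
        ("hip_l", "l5s1", ("y", "x"), "thigh_l"),
        ("knee_l", "hip_l", ("y",), "shank_l"),
        ("ankle_l", "knee_l", ("y",), "foot_l"),
        ("shoulder_r", "l5s1", ("y", "x"), "arm_r"),
        ("shoulder_l", "l5s1", ("y", "x"), "arm_l"),
    ],
    "c": [
        ("l5s1", None, ("y", "x", "z"), "trunk"),
        ("hip_r", "l5s1", ("y", "x", "z"), "thigh_r"),
        ("knee_r", "hip_r", ("y",), "shank_foot_r"),
        ("hip_l", "l5s1", ("y", "x", "z"), "thigh_l"),
        ("knee_l", "hip_l", ("y",), "shank_foot_l"),
        ("shoulder_r", "l5s1", ("y", "x", "z"), "arm_r"),
        ("shoulder_l", "l5s1", ("y", "x", "z"), "arm_l"),
    ],
    "d": [
        ("l5s1", None, ("y", "x", "z"), "trunk"),
        ("hip_r", "l5s1", ("y", "x", "z"), "thigh_r"),
        ("knee_r", "hip_r", ("y",), "shank_r"),
        ("ankle_r", "knee_r", ("y",), "foot_r"),
        ("hip_l", "l5s1", ("y", "x", "z"), "thigh_l"),
        ("knee_l", "hip_l", ("y",), "shank_l"),
        ("ankle_l", "knee_l", ("y",), "foot_l"),
        ("shoulder_r", "l5s1", ("y", "x", "z"), "arm_r"),
        ("shoulder_l", "l5s1", ("y", "x", "z"), "arm_l"),
    ],
}


def _lumped_offset(
    joint: str, parent_in_model: Optional[str], skeleton: Mapping[str, Sequence[float]]
) -> np.ndarray:
    """Offset of `joint` from its model parent, summing across skeleton
    joints that the model omits (e.g. hip->ankle when the knee is dropped)."""
    if parent_in_model is None:
        return np.zeros(3)
    total = np.zeros(3)
    cur = joint
    while cur != parent_in_model:
        total += np.asarray(skeleton[cur], dtype=float)
        cur = _SKELETON_PARENT[cur]
        if cur is None:
            raise ValueError(f"{parent_in_model!r} is not an ancestor of {joint!r}")
    return total


def build_preset(
    model_id: str, skeleton: Optional[Mapping[str, Sequence[float]]] = None
) -> KinematicModel:
    """Construct one of the four preset bodies.

    Parameters
    ----------
    model_id : {'a', 'b', 'c', 'd'}
    skeleton : optional mapping joint -> offset (m) at full granularity,
        overriding the neutral template (``DEFAULT_SKELETON_M``).
    """
    if model_id not in _PRESETS:
        raise ValueError(f"unknown preset {model_id!r}, expected one of {PRESET_IDS}")
    skel = dict(DEFAULT_SKELETON_M)
    if skeleton is not None:
        skel.update({k: tuple(v) for k, v in skeleton.items()})
    joints = []
    segment_of = {}
    for name, parent, dof, segment in _PRESETS[model_id]:
        joints.append(JointSpec(name, parent, _lumped_offset(name, parent, skel), dof))
        segment_of[name] = segment
    return KinematicModel(model_id, joints, segment_of)


_GIMBAL_TOL = 1e-9


def decompose_zxy(R: np.ndarray) -> Tuple[float, float, float]:
    """Angles (alpha, beta, gamma) with R = R_y(alpha) R_x(beta) R_z(gamma).

    Raises ``ValueError`` at gimbal lock (|cos beta| below 1e-9), where
    alpha and gamma are not separable.
    """
    R = np.asarray(R, dtype=float)
    s = float(np.clip(-R[1, 2], -1.0, 1.0))
    beta = float(np.arcsin(s))
    if abs(np.cos(beta)) < _GIMBAL_TOL:
        raise ValueError("gimbal lock: |cos(beta)| < 1e-9, ZXY angles undefined")
    alpha = float(np.arctan2(R[0, 2], R[2, 2]))
    gamma = float(np.arctan2(R[1, 0], R[1, 1]))
    return alpha, beta, gamma


_ANGLE_OF_AXIS = {"y": 0, "x": 1, "z": 2}  # index into (alpha, beta, gamma)


def project_posture(
    posture: Posture, source_model: KinematicModel, target_model: KinematicModel
) -> Posture:
    """Re-express a posture of a richer body on a simpler model.

    Each target joint's full rotation (as realized by the source body) is
    decomposed in the ZXY-fixed sequence and only the angle components the
    target DoF sequence names are kept; source joints absent from the
    target are dropped, their motion becoming unmodeled error by design.
    Postures hitting gimbal lock are returned with ``flagged=True`` and
    the offending angles zeroed.
    """
    out: Dict[str, Tuple[float, ...]] = {}
    flagged = False
    source_names = set(source_model.joint_names())
    for tj in target_model.joints:
        if tj.name not in source_names:
            raise ValueError(f"target joint {tj.name!r} does not exist in source model")
        sj = source_model.joint(tj.name)
        R = joint_rotation(sj.dof, posture.angles_for(sj.name, len(sj.dof)))
        try:
            abg = decompose_zxy(R)
        except ValueError:
            abg = (0.0, 0.0, 0.0)
            flagged = True
        out[tj.name] = tuple(abg[_ANGLE_OF_AXIS[ax]] for ax in tj.dof)
    return Posture(out, np.array(posture.root_position, float), flagged=flagged)


def model_to_yaml(model: KinematicModel) -> str:
    """Serialize a model to YAML (offsets in millimeters, as at every
    file boundary); round-trips exactly through ``model_from_yaml``."""
    doc = {
        "model_id": model.model_id,
        "joints": [
            {
                "name": j.name,
                "parent": j.parent,
                "offset_mm": [float(v) * 1000.0 for v in j.offset],
                "dof": "".join(j.dof),
                "segment": model.segment_of[j.name],
            }
            for j in model.joints
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> KinematicModel:
    doc = yaml.safe_load(text)
    joints = []
    segment_of = {}
    for j in doc["joints"]:
        joints.append(
            JointSpec(
                j["name"],
                j["parent"],
                np.asarray(j["offset_mm"], dtype=float) / 1000.0,
                tuple(j["dof"]),
            )
        )
        segment_of[j["name"]] = j["segment"]
    return KinematicModel(doc["model_id"], joints, segment_of)
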