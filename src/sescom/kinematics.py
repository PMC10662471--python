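"""Rotation algebra and forward kinematics for branched body models.

Conventions
-----------
Global frame: X anteroposterior (anterior positive), Y mediolateral,
Z vertical up.  Flexion/extension is rotation about Y, so a hinge-only
model moves exclusively in the X-Z (sagittal) plane and its ML
coordinate is constant -- the degeneracy the evaluation layer exploits.

Angles are radians and lengths are meters everywhere inside the
library; degrees and millimeters appear only at file boundaries.

The whole-body center of mass is the mass-weighted mean of the segment
centers of mass,

    CoM = (1/M) * sum_i m_i * C_i^G,

with each segment's global center C_i^G obtained by chaining
homogeneous transforms along the kinematic tree from the root joint.
This weighted sum is the brute-force oracle against which the serial
chain reparameterization (``sescom.sesc``) is checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .body_models import KinematicModel
    from .synthetic import SubjectParams

Axis = str  # 'x' | 'y' | 'z'

_AXES = ("x", "y", "z")


def rotation_about_axis(axis: Axis, angle: float) -> np.ndarray:
    """Elementary rotation matrix about a principal axis.

    Parameters
    ----------
    axis : {'x', 'y', 'z'}
    angle : float
        Rotation angle in radians.

    Returns
    -------
    (3, 3) ndarray, orthonormal with determinant +1.
    """
    if not np.isfinite(angle):
        raise ValueError(f"rotation angle must be finite, got {angle!r}")
    c, s = np.cos(angle), np.sin(angle)
    ax = axis.lower()
    if ax == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if ax == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if ax == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    raise ValueError(f"unknown axis {axis!r}, expected one of {_AXES}")


def joint_rotation(sequence: Sequence[Axis], angles: Sequence[float]) -> np.ndarray:
    """Compose a joint's rotation from its DoF sequence.

    The sequence is multiplied left to right: a 3-DoF ball joint with
    sequence ('y', 'x', 'z') yields R_y(alpha) @ R_x(beta) @ R_z(gamma),
    the ZXY-"fixed" convention used by IMU motion-capture exports.
    """
    if len(angles) != len(sequence):
        raise ValueError(
            f"angle count {len(angles)} does not match DoF sequence {tuple(sequence)}"
        )
    R = np.eye(3)
    for ax, ang in zip(sequence, angles):
        R = R @ rotation_about_axis(ax, ang)
    return R


@dataclass(frozen=True)
class Transform:
    """Rigid transform: p_global = rotation @ p_local + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, point: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(point, dtype=float) + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self then other in self's frame: (self * other)(p) = self(other(p))."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class Posture:
    """One static configuration: per-joint angle tuples plus root position.

    ``joint_angles`` maps joint name -> tuple of radians aligned with the
    joint's DoF sequence; ``root_position`` is d1, the root joint's
    location in the global frame (meters).
    """

    joint_angles: Dict[str, Tuple[float, ...]]
    root_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    flagged: bool = False  # set when angle extraction hit gimbal lock

    def angles_for(self, joint_name: str, n_dof: int) -> Tuple[float, ...]:
        try:
            angs = self.joint_angles[joint_name]
        except KeyError:
            raise ValueError(f"posture is missing angles for joint {joint_name!r}")
        if len(angs) != n_dof:
            raise ValueError(
                f"joint {joint_name!r} expects {n_dof} angles, got {len(angs)}"
            )
        return tuple(angs)


def forward_transforms(model: "KinematicModel", posture: Posture) -> Dict[str, Transform]:
    """Global transform of every joint frame.

    The root transform is (R_root, d1); each child's transform is the
    parent's composed with the constant parent-frame offset and the
    child's own joint rotation, i.e. the ordered product of homogeneous
    transforms along the unique root-to-joint path.
    """
    out: Dict[str, Transform] = {}
    for joint in model.joints:
        R_local = joint_rotation(
            joint.dof, posture.angles_for(joint.name, len(joint.dof))
        )
        if joint.parent is None:
            out[joint.name] = Transform(R_local, np.asarray(posture.root_position, float))
        else:
            parent_tf = out[joint.parent]
            out[joint.name] = parent_tf.compose(Transform(R_local, joint.offset))
    return out


def com_weighted_sum(
    model: "KinematicModel", params: "SubjectParams", posture: Posture
) -> np.ndarray:
    """Whole-body CoM by the mass-weighted segment sum (the oracle form).

    Each joint carries the segment rigidly attached distal to it; the
    segment's CoM sits at a constant local offset in the joint frame.
    """
    total = params.total_mass
    if not total > 0:
        raise ValueError(f"total mass must be positive, got {total}")
    acc = np.zeros(3)
    tfs = forward_transforms(model, posture)
    for joint in model.joints:
        seg = model.segment_of[joint.name]
        m = params.masses[seg]
        if m < 0:
            raise ValueError(f"segment {seg!r} has negative mass {m}")
        acc += m * tfs[joint.name].apply(params.com_offsets[seg])
    return acc / total


def is_rotation(R: np.ndarray, tol: float = 1e-10) -> bool:
    """Orthonormality and det +1 check used by invariant tests."""
    R = np.asarray(R)
    return (
        R.shape == (3, 3)
        and np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
    )
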