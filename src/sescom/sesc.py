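"""The statically equivalent serial chain (SESC) core.

A branched chain's center of mass can be rewritten as the end effector
of a virtual serial chain:

    CoM = d1 + [R_1 ... R_n] [v_1; ...; v_n] = d1 + B V,

where d1 is the root joint position, R_j is the global rotation of
joint j's frame (the ordered product of joint rotations along the
root->j path), and V stacks n constant 3-vectors of subject-specific
inertial parameters.  V is identified once per subject by least squares
from static postures; afterwards the full 3D CoM follows from joint
angles alone.

With only the horizontal CoM observed (force-plate center of pressure
in static stance), the vertical row of B is dropped and the x/y rows of
k postures are stacked; identifiability then requires at least
ceil(3n/2) postures.

The pseudoinverse is computed by SVD with a relative singular-value
cutoff of 1e-10 rather than through the normal equations, which square
the condition number; on well-conditioned systems the two agree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .body_models import KinematicModel
from .kinematics import Posture, joint_rotation

__all__ = [
    "Observation",
    "ObservationSet",
    "IdentificationResult",
    "RankDeficiencyError",
    "PostureShortageError",
    "build_B",
    "stack_full",
    "stack_partial",
    "true_sesc_vector",
    "identify_full",
    "identify_partial",
    "estimate_com",
    "min_postures",
]

_SV_RCOND = 1e-10


class RankDeficiencyError(RuntimeError):
    """Design matrix rank below the parameter count; no unique solution."""


class PostureShortageError(ValueError):
    """Fewer postures than the ceil(3n/2) identifiability minimum."""


@dataclass
class Observation:
    """One static posture with its horizontal CoM reference.

    ``cop`` is the (AP, ML) center of pressure in meters, already in the
    body-rooted global frame; ``true_com`` (3-vector, m) is carried only
    by synthetic data for scoring.
    """

    posture: Posture
    cop: np.ndarray
    true_com: Optional[np.ndarray] = None


@dataclass
class ObservationSet:
    observations: List[Observation]

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return ObservationSet(self.observations[idx])
        return self.observations[idx]

    def subset(self, indices: Sequence[int]) -> "ObservationSet":
        return ObservationSet([self.observations[i] for i in indices])


@dataclass
class IdentificationResult:
    """Identified SESC vector with least-squares diagnostics."""

    vector: np.ndarray  # length 3n, meters
    residual_rms: float  # meters, over the rows actually fitted
    condition_number: float
    rank: int
    n_rows: int
    n_params: int
    k_postures: int
    deficient: bool = False
    deficient_columns: List[int] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "n_params": self.n_params,
            "k_postures": self.k_postures,
            "n_rows": self.n_rows,
            "rank": self.rank,
            "condition_number": self.condition_number,
            "residual_rms_m": self.residual_rms,
            "deficient": self.deficient,
            "deficient_columns": list(self.deficient_columns),
        }


def min_postures(model: KinematicModel) -> int:
    """Minimum static-posture count for 2D (CoP) identification: ceil(3n/2)."""
    return math.ceil(3 * model.n_joints / 2)


def build_B(model: KinematicModel, posture: Posture) -> np.ndarray:
    """The 3 x 3n block row for one posture.

    Column block j is the global rotation of joint j's frame — the
    product of joint rotations along the root->j path, translations
    excluded.  With all angles zero B is n stacked identity blocks.
    """
    n = model.n_joints
    B = np.empty((3, 3 * n))
    globals_: dict = {}
    for j, joint in enumerate(model.joints):
        R_local = joint_rotation(joint.dof, posture.angles_for(joint.name, len(joint.dof)))
        if joint.parent is None:
            Rg = R_local
        else:
            Rg = globals_[joint.parent] @ R_local
        globals_[joint.name] = Rg
        B[:, 3 * j : 3 * j + 3] = Rg
    return B


def true_sesc_vector(model: KinematicModel, params) -> np.ndarray:
    """Ground-truth SESC vector from known segment masses and geometry.

    Closed form: v_j = ( m_j c_j + sum over children q of j of
    (subtree mass of q) * offset_q ) / M, where c_j is the local CoM of
    the segment attached to joint j and offset_q the constant child
    offset in j's frame.  Satisfies d1 + B V = weighted-segment CoM for
    every posture (the module's central oracle).
    """
    M = params.total_mass
    if not M > 0:
        raise ValueError(f"total mass must be positive, got {M}")

    subtree: dict = {}
    for joint in reversed(model.joints):  # children precede parents in reverse
        m = params.masses[model.segment_of[joint.name]]
        subtree[joint.name] = m + sum(subtree[c.name] for c in model.children_of(joint.name))

    V = np.zeros(3 * model.n_joints)
    for j, joint in enumerate(model.joints):
        seg = model.segment_of[joint.name]
        v = params.masses[seg] * np.asarray(params.com_offsets[seg], float)
        for child in model.children_of(joint.name):
            v = v + subtree[child.name] * child.offset
        V[3 * j : 3 * j + 3] = v / M
    return V


def _solve(
    A: np.ndarray, b: np.ndarray, k_postures: int, n_params: int
) -> IdentificationResult:
    sv = np.linalg.svd(A, compute_uv=False)
    tol = sv[0] * _SV_RCOND if sv.size else 0.0
    rank = int(np.sum(sv > tol))
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    V, _, _, _ = np.linalg.lstsq(A, b, rcond=_SV_RCOND)
    resid = A @ V - b
    rms = float(np.sqrt(np.mean(resid**2)))
    deficient = rank < n_params
    deficient_cols: List[int] = []
    if deficient:
        # columns with negligible projection onto the row space
        _, s_full, Vt = np.linalg.svd(A)
        null_basis = Vt[rank:]
        col_null_norm = np.linalg.norm(null_basis, axis=0)
        deficient_cols = [int(i) for i in np.flatnonzero(col_null_norm > 1e-8)]
    return IdentificationResult(
        vector=V,
        residual_rms=rms,
        condition_number=cond,
        rank=rank,
        n_rows=A.shape[0],
        n_params=n_params,
        k_postures=k_postures,
        deficient=deficient,
        deficient_columns=deficient_cols,
    )


def stack_full(
    model: KinematicModel, postures: Sequence[Posture]
) -> np.ndarray:
    """Stack the full 3-row B blocks of k postures into a 3k x 3n matrix."""
    return np.vstack([build_B(model, p) for p in postures])


def stack_partial(
    model: KinematicModel, postures: Sequence[Posture]
) -> np.ndarray:
    """Stack only the horizontal (AP=x, ML=y) rows: 2k x 3n."""
    return np.vstack([build_B(model, p)[:2] for p in postures])


def identify_full(B_stack: np.ndarray, com_targets: np.ndarray) -> IdentificationResult:
    """Identify V from full 3D CoM observations (root position already
    subtracted from the targets).

    ``B_stack`` is 3k x 3n, ``com_targets`` the matching stacked
    CoM - d1 values (flat, length 3k).  Raises ``RankDeficiencyError``
    when rank(B) < 3n, reporting the deficiency margin.
    """
    b = np.asarray(com_targets, dtype=float).ravel()
    n_params = B_stack.shape[1]
    if B_stack.shape[0] < n_params:
        raise PostureShortageError(
            f"{B_stack.shape[0]} rows < {n_params} parameters: more postures needed"
        )
    res = _solve(B_stack, b, k_postures=B_stack.shape[0] // 3, n_params=n_params)
    if res.deficient:
        raise RankDeficiencyError(
            f"design matrix rank {res.rank} < {n_params} parameters "
            f"(deficiency margin {n_params - res.rank}); postures are not diverse enough"
        )
    return res


def identify_partial(
    observations: ObservationSet,
    model: KinematicModel,
    *,
    allow_shortage: bool = False,
) -> IdentificationResult:
    """Identify V from static postures and 2D CoP (the practical route).

    Stacks the AP and ML rows of each posture's B against
    CoP - d1 horizontals and solves by SVD pseudoinverse.  Below the
    ceil(3n/2) posture minimum a ``PostureShortageError`` is raised
    unless ``allow_shortage``.  Rank deficiency (inevitable for a
    hinge-only body, whose ML row is constant) produces a warning with
    the deficient columns; the minimum-norm solution is still returned
    and remains valid for prediction.
    """
    k = len(observations)
    kmin = min_postures(model)
    if k < kmin and not allow_shortage:
        raise PostureShortageError(
            f"{k} postures < minimum {kmin} (= ceil(3n/2) with n={model.n_joints} joints)"
        )
    rows = []
    rhs = []
    for obs in observations:
        B = build_B(model, obs.posture)
        rows.append(B[:2])
        d1 = np.asarray(obs.posture.root_position, float)
        rhs.extend(np.asarray(obs.cop, float)[:2] - d1[:2])
    A = np.vstack(rows)
    res = _solve(A, np.asarray(rhs), k_postures=k, n_params=3 * model.n_joints)
    if res.deficient:
        warnings.warn(
            f"CoP identification is rank deficient (rank {res.rank} of {res.n_params}); "
            f"columns {res.deficient_columns} are not identifiable from these postures. "
            "Returning the minimum-norm solution.",
            RuntimeWarning,
            stacklevel=2,
        )
    return res


def estimate_com(model: KinematicModel, V: np.ndarray, posture: Posture) -> np.ndarray:
    """Full 3D CoM from joint angles alone: d1 + B(posture) V."""
    V = np.asarray(V, dtype=float).ravel()
    if V.size != 3 * model.n_joints:
        raise ValueError(
            f"SESC vector length {V.size} does not match 3x{model.n_joints} joints"
        )
    return np.asarray(posture.root_position, float) + build_B(model, posture) @ V
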