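"""Synthetic subjects, postures, observations and raw sessions.

Everything downstream is testable without real recordings because the
generator produces data with known ground truth and with the same
statistical structure an identification session has: a cohort of
subjects, each holding on the order of a hundred distinct static
postures; the force-plate center of pressure equal to the true CoM's
horizontal projection plus noise; joint angles read with small sensor
noise.  Defaults mirror a typical adult cohort protocol: 18 subjects,
98 postures each, CoP noise 3 mm and angle noise 0.75 deg — half the
static-detection criteria (6 mm, 1.5 deg) so scheduled holds are
reliably accepted.

The truth body defaults to the richest preset (model d); simpler models
fitted to its output incur systematic error from their missing DoFs,
which is exactly the model-complexity effect under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import body_models
from .body_models import DEFAULT_SKELETON_M, KinematicModel, build_preset
from .kinematics import Posture, com_weighted_sum
from .sesc import Observation, ObservationSet

__all__ = [
    "SubjectParams",
    "Subject",
    "NoiseSpec",
    "SubjectVariation",
    "CohortConfig",
    "DEFAULT_RANGES_DEG",
    "default_ranges",
    "sample_subject",
    "params_for_model",
    "sample_postures",
    "generate_observations",
    "generate_timeseries",
    "simulate_cohort",
    "SessionRecord",
]


@dataclass
class SubjectParams:
    """Per-segment inertial parameters for one model granularity.

    ``masses`` in kg; ``com_offsets`` the segment CoM in its joint frame
    (m).  Ground truth for synthesis and for the closed-form SESC vector.
    """

    masses: Dict[str, float]
    com_offsets: Dict[str, np.ndarray]

    @property
    def total_mass(self) -> float:
        return float(sum(self.masses.values()))


# Neutral template at full (model d) granularity: mass fractions and
# segment CoM offsets (m) in the attached joint's frame.
_TEMPLATE_MASS_FRACTIONS: Dict[str, float] = {
    "trunk": 0.578,  # trunk + head + pelvis
    "thigh_r": 0.100,
    "thigh_l": 0.100,
    "shank_r": 0.0465,
    "shank_l": 0.0465,
    "foot_r": 0.0145,
    "foot_l": 0.0145,
    "arm_r": 0.050,
    "arm_l": 0.050,
}
_TEMPLATE_SEG_COM_M: Dict[str, Tuple[float, float, float]] = {
    "trunk": (0.0, 0.0, 0.25),
    "thigh_r": (0.0, 0.0, -0.19),
    "thigh_l": (0.0, 0.0, -0.19),
    "shank_r": (0.0, 0.0, -0.18),
    "shank_l": (0.0, 0.0, -0.18),
    "foot_r": (0.06, 0.0, -0.05),
    "foot_l": (0.06, 0.0, -0.05),
    "arm_r": (0.0, 0.0, -0.25),
    "arm_l": (0.0, 0.0, -0.25),
}
_TEMPLATE_MASS_KG = 75.0

#: How coarse-model segments lump the full-granularity ones.  Each entry
#: maps a lumped segment to (parts, attach joint of each part's chain).
_LUMPING: Dict[str, List[str]] = {
    "leg_r": ["thigh_r", "shank_r"],
    "leg_l": ["thigh_l", "shank_l"],
    "shank_foot_r": ["shank_r", "foot_r"],
    "shank_foot_l": ["shank_l", "foot_l"],
}
# chain offsets needed to express a lumped part in the lump's root frame
_PART_PARENT_OFFSET_KEY: Dict[str, str] = {
    "shank_r": "knee_r",
    "shank_l": "knee_l",
    "foot_r": "ankle_r",
    "foot_l": "ankle_l",
}


@dataclass
class SubjectVariation:
    """Sampling ranges around the neutral template (uniform draws)."""

    mass_kg: Tuple[float, float] = (55.0, 95.0)
    stature_scale: Tuple[float, float] = (0.90, 1.10)
    mass_fraction_jitter: float = 0.10  # relative, renormalized after

    def validate(self) -> None:
        if self.mass_kg[1] < self.mass_kg[0] or self.mass_kg[0] <= 0:
            raise ValueError(f"degenerate mass range {self.mass_kg}")
        if self.stature_scale[1] < self.stature_scale[0] or self.stature_scale[0] <= 0:
            raise ValueError(f"degenerate stature range {self.stature_scale}")
        if self.mass_fraction_jitter < 0:
            raise ValueError("mass_fraction_jitter must be >= 0")


@dataclass
class Subject:
    """Full-granularity ground truth for one synthetic individual."""

    subject_id: str
    skeleton: Dict[str, np.ndarray]  # joint offsets (m), model-d granularity
    seg_masses: Dict[str, float]  # kg, model-d segments
    seg_coms: Dict[str, np.ndarray]  # m, in joint frame

    @property
    def total_mass(self) -> float:
        return float(sum(self.seg_masses.values()))

    def model(self, model_id: str) -> KinematicModel:
        return build_preset(model_id, self.skeleton)

    def params_for(self, model: Union[str, KinematicModel]) -> SubjectParams:
        mid = model if isinstance(model, str) else model.model_id
        return params_for_model(self, mid)


def sample_subject(
    rng: Union[int, np.random.Generator],
    subject_id: str = "s00",
    variation: Optional[SubjectVariation] = None,
) -> Subject:
    """Draw one subject around the neutral template, deterministic per seed."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    var = variation if variation is not None else SubjectVariation()
    var.validate()

    mass = rng.uniform(*var.mass_kg)
    scale = rng.uniform(*var.stature_scale)
    fracs = {}
    for seg, f in _TEMPLATE_MASS_FRACTIONS.items():
        jitter = rng.uniform(-var.mass_fraction_jitter, var.mass_fraction_jitter)
        fracs[seg] = f * (1.0 + jitter)
    norm = sum(fracs.values())
    seg_masses = {seg: mass * f / norm for seg, f in fracs.items()}
    skeleton = {j: scale * np.asarray(o, float) for j, o in DEFAULT_SKELETON_M.items()}
    seg_coms = {s: scale * np.asarray(c, float) for s, c in _TEMPLATE_SEG_COM_M.items()}
    return Subject(subject_id, skeleton, seg_masses, seg_coms)


def params_for_model(subject: Subject, model_id: str) -> SubjectParams:
    """Per-model segment parameters, lumping across joints the model omits.

    A lumped segment (e.g. thigh+shank for the hinge-only body) gets the
    summed mass and the mass-weighted CoM evaluated in the neutral
    (straight) configuration, which is exact only when the omitted joint
    does not move — the modeling error simpler bodies commit by design.
    """
    model = subject.model(model_id)
    masses: Dict[str, float] = {}
    coms: Dict[str, np.ndarray] = {}
    for seg in model.segment_of.values():
        if seg in subject.seg_masses:
            masses[seg] = subject.seg_masses[seg]
            coms[seg] = np.array(subject.seg_coms[seg])
        else:
            parts = _LUMPING[seg]
            m_tot = sum(subject.seg_masses[p] for p in parts)
            acc = np.zeros(3)
            chain_offset = np.zeros(3)
            for i, part in enumerate(parts):
                if i > 0:
                    chain_offset = chain_offset + subject.skeleton[
                        _PART_PARENT_OFFSET_KEY[part]
                    ]
                acc += subject.seg_masses[part] * (chain_offset + subject.seg_coms[part])
            masses[seg] = m_tot
            coms[seg] = acc / m_tot if m_tot > 0 else np.zeros(3)
    return SubjectParams(masses, coms)


# Conservative healthy range-of-motion subsets per joint type (degrees),
# keyed by rotation axis.  Configurable per joint in sampling calls.
DEFAULT_RANGES_DEG: Dict[str, Dict[str, Tuple[float, float]]] = {
    "l5s1": {"y": (-20.0, 40.0), "x": (-15.0, 15.0), "z": (-20.0, 20.0)},
    "hip": {"y": (-15.0, 60.0), "x": (-20.0, 20.0), "z": (-15.0, 15.0)},
    "knee": {"y": (-70.0, 0.0)},
    "ankle": {"y": (-20.0, 20.0)},
    "shoulder": {"y": (-30.0, 90.0), "x": (-60.0, 10.0), "z": (-30.0, 30.0)},
}


def _joint_type(name: str) -> str:
    return name.rsplit("_", 1)[0] if name.rsplit("_", 1)[0] in (
        "hip",
        "knee",
        "ankle",
        "shoulder",
    ) else name


def default_ranges(model: KinematicModel) -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Per-joint, per-axis sampling ranges (degrees) for a model."""
    generic = {"y": (-45.0, 45.0), "x": (-45.0, 45.0), "z": (-45.0, 45.0)}
    out = {}
    for j in model.joints:
        table = DEFAULT_RANGES_DEG.get(_joint_type(j.name), generic)
        out[j.name] = {ax: table[ax] for ax in j.dof}
    return out


def sample_postures(
    model: KinematicModel,
    k: int,
    rng: Union[int, np.random.Generator],
    ranges_deg: Optional[Mapping[str, Mapping[str, Tuple[float, float]]]] = None,
) -> List[Posture]:
    """Independent uniform draws per DoF within per-joint ranges."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ranges = ranges_deg if ranges_deg is not None else default_ranges(model)
    postures = []
    for _ in range(k):
        angs: Dict[str, Tuple[float, ...]] = {}
        for j in model.joints:
            vals = []
            for ax in j.dof:
                lo, hi = ranges[j.name][ax]
                if hi < lo:
                    raise ValueError(f"empty range for {j.name}/{ax}: ({lo}, {hi})")
                vals.append(np.deg2rad(rng.uniform(lo, hi)))
            angs[j.name] = tuple(vals)
        postures.append(Posture(angs))
    return postures


@dataclass
class NoiseSpec:
    """Measurement noise (Gaussian, zero-mean).

    Defaults are half the static-posture criteria (CoP SD < 6 mm,
    angle SD < 1.5 deg) so generated holds satisfy them with margin.
    """

    cop_noise_sd_mm: float = 3.0
    angle_noise_sd_deg: float = 0.75

    def __post_init__(self):
        if self.cop_noise_sd_mm < 0 or self.angle_noise_sd_deg < 0:
            raise ValueError("noise SDs must be >= 0")

    def scaled(self, factor: float) -> "NoiseSpec":
        return NoiseSpec(self.cop_noise_sd_mm * factor, self.angle_noise_sd_deg * factor)


def _perturb_posture(
    posture: Posture, sd_rad: float, rng: np.random.Generator
) -> Posture:
    if sd_rad == 0:
        return Posture(dict(posture.joint_angles), np.array(posture.root_position))
    angs = {
        name: tuple(a + rng.normal(0.0, sd_rad) for a in vals)
        for name, vals in posture.joint_angles.items()
    }
    return Posture(angs, np.array(posture.root_position))


def generate_observations(
    subject: Subject,
    truth_model: KinematicModel,
    postures: Sequence[Posture],
    noise: NoiseSpec,
    rng: Union[int, np.random.Generator],
) -> ObservationSet:
    """Static observations: CoP = true horizontal CoM + noise.

    The recorded joint angles carry their own sensor noise; the exact 3D
    CoM (from the weighted-segment sum on the truth body) is retained
    for scoring only.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params = subject.params_for(truth_model)
    sd_cop_m = noise.cop_noise_sd_mm / 1000.0
    sd_ang_rad = np.deg2rad(noise.angle_noise_sd_deg)
    obs = []
    for p in postures:
        true_com = com_weighted_sum(truth_model, params, p)
        cop = true_com[:2] + rng.normal(0.0, sd_cop_m, size=2) if sd_cop_m > 0 else true_com[:2].copy()
        measured = _perturb_posture(p, sd_ang_rad, rng)
        obs.append(Observation(posture=measured, cop=cop, true_com=true_com))
    return ObservationSet(obs)


@dataclass
class SessionRecord:
    """Raw synthetic session plus the schedule that produced it."""

    angle_rate_hz: float
    cop_rate_hz: float
    angle_channels: Dict[str, np.ndarray]  # degrees
    cop_channels: Dict[str, np.ndarray]  # mm, plate frame
    l5_channels: Dict[str, np.ndarray]  # mm, plate frame (constant here)
    scheduled_postures: List[Posture]
    scheduled_coms: List[np.ndarray]  # m, body frame
    hold_spans_s: List[Tuple[float, float]]


def generate_timeseries(
    subject: Subject,
    truth_model: KinematicModel,
    posture_schedule: Sequence[Posture],
    noise: NoiseSpec,
    rng: Union[int, np.random.Generator],
    hold_s: float = 6.0,
    ramp_s: float = 2.0,
    rates: Tuple[float, float] = (60.0, 1000.0),
    plate_offset_mm: Tuple[float, float] = (0.0, 0.0),
    detection_window_s: float = 1.0,
) -> SessionRecord:
    """Raw session: scheduled holds joined by smooth (cosine) ramps.

    Joint angles are emitted at the mocap rate, CoP at the force-plate
    rate; noise is added everywhere at the given SDs.  The schedule is
    recorded so static-detection round trips can be scored exactly.
    """
    if not posture_schedule:
        raise ValueError("posture schedule is empty")
    if hold_s < detection_window_s:
        raise ValueError(f"hold_s={hold_s} shorter than the detection window")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    angle_rate, cop_rate = rates
    params = subject.params_for(truth_model)

    # keyframes: angle value per channel during each hold
    channels = [
        (j.name, ax_i, ax)
        for j in truth_model.joints
        for ax_i, ax in enumerate(j.dof)
    ]
    key_angles = np.array(
        [
            [p.joint_angles[name][ax_i] for (name, ax_i, _) in channels]
            for p in posture_schedule
        ]
    )  # (n_holds, n_channels), radians
    coms = [com_weighted_sum(truth_model, params, p) for p in posture_schedule]

    n_holds = len(posture_schedule)
    total_s = n_holds * hold_s + (n_holds - 1) * ramp_s
    hold_spans = [
        (i * (hold_s + ramp_s), i * (hold_s + ramp_s) + hold_s) for i in range(n_holds)
    ]

    def trajectory(t: np.ndarray, keys: np.ndarray) -> np.ndarray:
        """Piecewise hold/cosine-ramp interpolation of one channel."""
        out = np.empty_like(t)
        seg = hold_s + ramp_s
        idx = np.minimum((t // seg).astype(int), n_holds - 1)
        t_in = t - idx * seg
        ramping = (t_in > hold_s) & (idx < n_holds - 1)
        out = keys[idx]
        if np.any(ramping):
            u = (t_in[ramping] - hold_s) / ramp_s
            w = 0.5 - 0.5 * np.cos(np.pi * u)  # smooth 0->1
            out = out.astype(float)
            out[ramping] = (1 - w) * keys[idx[ramping]] + w * keys[idx[ramping] + 1]
        return out

    t_ang = np.arange(0.0, total_s, 1.0 / angle_rate)
    t_cop = np.arange(0.0, total_s, 1.0 / cop_rate)

    sd_ang = noise.angle_noise_sd_deg
    angle_channels = {}
    for c_i, (name, ax_i, ax) in enumerate(channels):
        clean = np.rad2deg(trajectory(t_ang, key_angles[:, c_i]))
        angle_channels[f"{name}_{ax}"] = clean + rng.normal(0.0, sd_ang, size=clean.shape)

    com_keys = np.array(coms)  # (n_holds, 3), meters
    sd_cop = noise.cop_noise_sd_mm
    cop_channels = {}
    for ax_i, ax in enumerate(("x", "y")):
        clean = 1000.0 * trajectory(t_cop, com_keys[:, ax_i]) + plate_offset_mm[ax_i]
        cop_channels[f"cop_{ax}"] = clean + rng.normal(0.0, sd_cop, size=clean.shape)

    l5_channels = {
        "l5_x": np.full(t_cop.shape, float(plate_offset_mm[0])),
        "l5_y": np.full(t_cop.shape, float(plate_offset_mm[1])),
        "l5_z": np.zeros(t_cop.shape),
    }
    return SessionRecord(
        angle_rate_hz=angle_rate,
        cop_rate_hz=cop_rate,
        angle_channels=angle_channels,
        cop_channels=cop_channels,
        l5_channels=l5_channels,
        scheduled_postures=list(posture_schedule),
        scheduled_coms=coms,
        hold_spans_s=hold_spans,
    )


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_subjects: int = 18
    postures_per_subject: int = 98
    truth_model_id: str = "d"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    train_fraction: float = 0.75
    variation: SubjectVariation = field(default_factory=SubjectVariation)
    ranges_deg: Optional[Dict[str, Dict[str, Tuple[float, float]]]] = None

    def validate(self) -> None:
        if self.n_subjects < 1 or self.postures_per_subject < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.truth_model_id not in body_models.PRESET_IDS:
            raise ValueError(f"unknown truth model {self.truth_model_id!r}")


@dataclass
class SubjectData:
    subject: Subject
    truth_model: KinematicModel
    observations: ObservationSet


def simulate_cohort(
    config: CohortConfig, seed: Union[int, np.random.Generator]
) -> List[SubjectData]:
    """Generate the whole cohort, deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for i in range(config.n_subjects):
        subject = sample_subject(rng, subject_id=f"s{i:02d}", variation=config.variation)
        truth_model = subject.model(config.truth_model_id)
        postures = sample_postures(
            truth_model, config.postures_per_subject, rng, config.ranges_deg
        )
        obs = generate_observations(subject, truth_model, postures, config.noise, rng)
        out.append(SubjectData(subject, truth_model, obs))
    return out
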