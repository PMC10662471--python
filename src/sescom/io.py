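"""File formats and run configuration.

Boundary conventions: CSV for tables, YAML for configuration, JSON for
reports and manifests; angles in degrees and lengths in millimeters in
every file (meters and radians only inside the library).

Posture tables are long-format CSV with columns
``subject_id, posture_id, channel, value`` where channels are
``<joint>_<axis>`` (deg), ``cop_x``/``cop_y`` (mm), ``root_x/y/z`` (mm)
and optionally ``true_com_x/y/z`` (mm, synthetic data only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .body_models import KinematicModel
from .kinematics import Posture
from .preprocessing import TimeSeries
from .sesc import Observation, ObservationSet

__all__ = [
    "SchemaError",
    "RunConfig",
    "load_config",
    "observations_to_frame",
    "frame_to_observations",
    "write_observations_csv",
    "read_observations_csv",
    "write_sesc_vector_csv",
    "read_sesc_vector_csv",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_report_json",
]


class SchemaError(ValueError):
    """A file or config does not match its declared schema."""


_MM = 1000.0


def observations_to_frame(
    obs_by_subject: Mapping[str, ObservationSet], model: KinematicModel
) -> pd.DataFrame:
    """Long-format posture table (degrees / millimeters)."""
    rows = []
    for sid, obs_set in obs_by_subject.items():
        for pid, obs in enumerate(obs_set):
            p = obs.posture

            def put(channel: str, value: float):
                rows.append(
                    {"subject_id": sid, "posture_id": pid, "channel": channel,
                     "value": float(value)}
                )

            for j in model.joints:
                for ax, ang in zip(j.dof, p.joint_angles[j.name]):
                    put(f"{j.name}_{ax}", np.rad2deg(ang))
            put("cop_x", obs.cop[0] * _MM)
            put("cop_y", obs.cop[1] * _MM)
            for ax_i, ax in enumerate(("x", "y", "z")):
                put(f"root_{ax}", p.root_position[ax_i] * _MM)
            if obs.true_com is not None:
                for ax_i, ax in enumerate(("x", "y", "z")):
                    put(f"true_com_{ax}", obs.true_com[ax_i] * _MM)
    return pd.DataFrame(rows)


def frame_to_observations(
    df: pd.DataFrame, model: KinematicModel
) -> Dict[str, ObservationSet]:
    """Inverse of :func:`observations_to_frame`."""
    required = {"subject_id", "posture_id", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"posture table is missing columns {sorted(missing)}")
    out: Dict[str, ObservationSet] = {}
    for sid, sub in df.groupby("subject_id", sort=True):
        obs_list: List[Observation] = []
        for pid, grp in sub.groupby("posture_id", sort=True):
            vals = dict(zip(grp["channel"], grp["value"]))
            angles: Dict[str, Tuple[float, ...]] = {}
            for j in model.joints:
                try:
                    angles[j.name] = tuple(
                        np.deg2rad(vals[f"{j.name}_{ax}"]) for ax in j.dof
                    )
                except KeyError as e:
                    raise SchemaError(
                        f"subject {sid} posture {pid}: missing channel {e.args[0]!r}"
                    ) from None
            if "cop_x" not in vals or "cop_y" not in vals:
                raise SchemaError(
                    f"subject {sid} posture {pid}: missing CoP channel(s)"
                )
            root = np.array(
                [vals.get(f"root_{ax}", 0.0) for ax in ("x", "y", "z")]
            ) / _MM
            cop = np.array([vals["cop_x"], vals["cop_y"]]) / _MM
            true_com = None
            if all(f"true_com_{ax}" in vals for ax in ("x", "y", "z")):
                true_com = (
                    np.array([vals[f"true_com_{ax}"] for ax in ("x", "y", "z")]) / _MM
                )
            obs_list.append(
                Observation(Posture(angles, root), cop, true_com)
            )
        out[str(sid)] = ObservationSet(obs_list)
    return out


def write_observations_csv(
    path: Union[str, Path],
    obs_by_subject: Mapping[str, ObservationSet],
    model: KinematicModel,
) -> None:
    observations_to_frame(obs_by_subject, model).to_csv(path, index=False)


def read_observations_csv(
    path: Union[str, Path], model: KinematicModel
) -> Dict[str, ObservationSet]:
    return frame_to_observations(pd.read_csv(path), model)


def write_sesc_vector_csv(
    path: Union[str, Path], model: KinematicModel, V: np.ndarray
) -> None:
    """SESC vector as (joint, component, value_mm) rows."""
    V = np.asarray(V, float).ravel()
    rows = []
    for j_i, joint in enumerate(model.joints):
        for c_i, comp in enumerate(("x", "y", "z")):
            rows.append(
                {"joint": joint.name, "component": comp,
                 "value_mm": V[3 * j_i + c_i] * _MM}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sesc_vector_csv(path: Union[str, Path], model: KinematicModel) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"joint", "component", "value_mm"}
    if not required <= set(df.columns):
        raise SchemaError(f"SESC vector file must have columns {sorted(required)}")
    lut = {(r["joint"], r["component"]): r["value_mm"] for _, r in df.iterrows()}
    V = np.empty(3 * model.n_joints)
    for j_i, joint in enumerate(model.joints):
        for c_i, comp in enumerate(("x", "y", "z")):
            try:
                V[3 * j_i + c_i] = lut[(joint.name, comp)] / _MM
            except KeyError:
                raise SchemaError(
                    f"SESC vector file missing entry for ({joint.name}, {comp})"
                ) from None
    return V


def write_timeseries_csv(path: Union[str, Path], series: TimeSeries) -> None:
    df = series.data.copy()
    df.insert(0, "time_s", series.time_s)
    df.to_csv(path, index=False)


def read_timeseries_csv(path: Union[str, Path]) -> TimeSeries:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError("time-series CSV must start with a 'time_s' column")
    t = df.pop("time_s").to_numpy()
    if len(t) < 2:
        raise SchemaError("time-series CSV needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SchemaError("time-series CSV must be uniformly sampled")
    return TimeSeries(rate_hz=1.0 / float(dt[0]), data=df)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; defaults are the study conditions."""

    models: Tuple[str, ...] = ("a", "b", "c", "d")
    filter_order: int = 4
    filter_cutoff_hz: float = 10.0
    target_rate_hz: float = 60.0
    static_window_s: float = 1.0
    angle_sd_max_deg: float = 1.5
    cop_sd_max_mm: float = 6.0
    min_hold_s: float = 5.0
    train_fraction: float = 0.75
    seed: int = 0
    # cohort block (simulation)
    n_subjects: int = 18
    postures_per_subject: int = 98
    truth_model_id: str = "d"
    cop_noise_sd_mm: float = 3.0
    angle_noise_sd_deg: float = 0.75

    _POSITIVE = (
        "filter_order", "filter_cutoff_hz", "target_rate_hz", "static_window_s",
        "angle_sd_max_deg", "cop_sd_max_mm", "min_hold_s",
        "n_subjects", "postures_per_subject",
    )

    def validate(self) -> None:
        for key in self._POSITIVE:
            if not getattr(self, key) > 0:
                raise SchemaError(f"config key {key!r} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise SchemaError("config key 'train_fraction' must lie in (0, 1)")
        for m in self.models:
            if m not in ("a", "b", "c", "d"):
                raise SchemaError(f"config key 'models' has unknown model id {m!r}")
        if self.truth_model_id not in ("a", "b", "c", "d"):
            raise SchemaError("config key 'truth_model_id' has an unknown model id")
        if self.cop_noise_sd_mm < 0 or self.angle_noise_sd_deg < 0:
            raise SchemaError("noise SD config keys must be >= 0")

    def provenance(self) -> dict:
        """Every defaulted parameter, for the report's provenance block."""
        return asdict(self)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise SchemaError("config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    for key in doc:
        if key not in known or key.startswith("_"):
            raise SchemaError(f"unknown config key {key!r}")
    if "models" in doc:
        doc["models"] = tuple(doc["models"])
    cfg = RunConfig(**doc)
    cfg.validate()
    return cfg


def write_report_json(path: Union[str, Path], report: Mapping) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=default))
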