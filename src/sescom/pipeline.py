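"""End-to-end orchestration: simulate -> identify per model -> estimate
-> evaluate, mirroring how an identification session is processed.

The fitted models never see the truth body's geometry or masses: each
one receives only the projected joint angles and the CoP, identifies
its own SESC vector on the training split, and is scored on held-out
postures.  Evaluation compares horizontal estimates against the CoP
reference (what a real session can measure) and, for synthetic data,
additionally against the exact 3D CoM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import io as sio
from .body_models import KinematicModel, build_preset, project_posture
from .evaluation import PairedSeries, bland_altman, compare_models, rms_error
from .preprocessing import split_postures
from .sesc import (
    IdentificationResult,
    ObservationSet,
    estimate_com,
    identify_partial,
    min_postures,
)
from .synthetic import CohortConfig, NoiseSpec, SubjectData, SubjectVariation, simulate_cohort

__all__ = [
    "SubjectFit",
    "fit_subject",
    "CohortResult",
    "run_cohort",
    "simulate_to_dir",
    "run_from_dir",
    "complexity_replicates",
]

_MM = 1000.0


@dataclass
class SubjectFit:
    """One subject x one fitted model, scored on held-out postures."""

    subject_id: str
    model_id: str
    identification: IdentificationResult
    estimates_mm: np.ndarray  # (n_test, 3) full 3D estimates
    cop_reference_mm: np.ndarray  # (n_test, 2) held-out CoP (AP, ML)
    true_com_mm: Optional[np.ndarray]  # (n_test, 3) or None

    @property
    def holdout_rms_ap_mm(self) -> float:
        d = self.estimates_mm[:, 0] - self.cop_reference_mm[:, 0]
        return float(np.sqrt(np.mean(d**2)))

    @property
    def holdout_rms_ml_mm(self) -> float:
        d = self.estimates_mm[:, 1] - self.cop_reference_mm[:, 1]
        return float(np.sqrt(np.mean(d**2)))

    @property
    def holdout_rms_3d_mm(self) -> Optional[float]:
        if self.true_com_mm is None:
            return None
        d = self.estimates_mm - self.true_com_mm
        return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def fit_subject(
    observations: ObservationSet,
    truth_model: KinematicModel,
    model_id: str,
    subject_id: str = "s00",
    train_fraction: float = 0.75,
    seed: int = 0,
) -> SubjectFit:
    """Project, split, identify, and score one fitted model.

    The split is deterministic per (seed, subject, model-independent):
    every model sees the same train/test partition, which preserves the
    per-subject pairing for cross-model comparisons.
    """
    fitted = build_preset(model_id)
    projected = ObservationSet(
        [
            type(obs)(
                posture=project_posture(obs.posture, truth_model, fitted),
                cop=obs.cop,
                true_com=obs.true_com,
            )
            for obs in observations
        ]
    )
    idx_train, idx_test = split_postures(list(range(len(projected))), train_fraction, seed)
    train = projected.subset(idx_train)
    test = projected.subset(idx_test)
    with warnings.catch_warnings():
        # hinge-only bodies are expectedly rank deficient from CoP alone
        warnings.simplefilter("ignore", RuntimeWarning)
        ident = identify_partial(train, fitted)
    est = np.array([estimate_com(fitted, ident.vector, o.posture) for o in test])
    cop = np.array([o.cop for o in test])
    true = (
        np.array([o.true_com for o in test])
        if all(o.true_com is not None for o in test)
        else None
    )
    return SubjectFit(
        subject_id=subject_id,
        model_id=model_id,
        identification=ident,
        estimates_mm=est * _MM,
        cop_reference_mm=cop * _MM,
        true_com_mm=None if true is None else true * _MM,
    )


@dataclass
class CohortResult:
    fits: List[SubjectFit]
    paired: Dict[str, Dict[str, PairedSeries]]  # model -> axis -> pooled pairs

    def cohort_mean_rms(self, model_id: str, axis: str) -> float:
        """Mean over subjects of per-subject held-out RMS (mm)."""
        vals = [
            f.holdout_rms_ap_mm if axis == "AP" else f.holdout_rms_ml_mm
            for f in self.fits
            if f.model_id == model_id
        ]
        return float(np.mean(vals))

    def comparison(self):
        return compare_models(self.paired)


def run_cohort(
    cohort: Sequence[SubjectData],
    model_ids: Sequence[str] = ("a", "b", "c", "d"),
    train_fraction: float = 0.75,
    seed: int = 0,
) -> CohortResult:
    """Fit every requested model to every subject and pool the pairs."""
    fits: List[SubjectFit] = []
    for s_i, sd in enumerate(cohort):
        for mid in model_ids:
            fits.append(
                fit_subject(
                    sd.observations,
                    sd.truth_model,
                    mid,
                    subject_id=sd.subject.subject_id,
                    train_fraction=train_fraction,
                    seed=seed + s_i,  # same split for all models of a subject
                )
            )
    paired: Dict[str, Dict[str, PairedSeries]] = {}
    for mid in model_ids:
        mfits = [f for f in fits if f.model_id == mid]
        est = np.concatenate([f.estimates_mm for f in mfits])
        ref = np.concatenate([f.cop_reference_mm for f in mfits])
        subj = np.concatenate(
            [np.repeat(f.subject_id, len(f.estimates_mm)) for f in mfits]
        )
        paired[mid] = {
            "AP": PairedSeries(est[:, 0], ref[:, 0], subj, axis="AP"),
            "ML": PairedSeries(est[:, 1], ref[:, 1], subj, axis="ML"),
        }
    return CohortResult(fits, paired)


def _cohort_config(cfg: sio.RunConfig) -> CohortConfig:
    return CohortConfig(
        n_subjects=cfg.n_subjects,
        postures_per_subject=cfg.postures_per_subject,
        truth_model_id=cfg.truth_model_id,
        noise=NoiseSpec(cfg.cop_noise_sd_mm, cfg.angle_noise_sd_deg),
        train_fraction=cfg.train_fraction,
    )


def simulate_to_dir(cfg: sio.RunConfig, seed: int, outdir: Union[str, Path]) -> Path:
    """Emit a cohort dataset: posture table CSV + manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(_cohort_config(cfg), seed)
    truth_model = cohort[0].truth_model
    obs_by_subject = {sd.subject.subject_id: sd.observations for sd in cohort}
    sio.write_observations_csv(outdir / "postures.csv", obs_by_subject, truth_model)
    from .sesc import true_sesc_vector  # local import: avoid cycle at module load

    manifest = {
        "seed": seed,
        "truth_model_id": cfg.truth_model_id,
        "provenance": cfg.provenance(),
        "subjects": {
            sd.subject.subject_id: {
                "total_mass_kg": sd.subject.total_mass,
                "true_sesc_vector_mm": (
                    true_sesc_vector(sd.truth_model, sd.subject.params_for(sd.truth_model))
                    * _MM
                ).tolist(),
            }
            for sd in cohort
        },
    }
    sio.write_report_json(outdir / "manifest.json", manifest)
    return outdir


def run_from_dir(
    dataset: Union[str, Path], cfg: sio.RunConfig, outdir: Union[str, Path]
) -> dict:
    """Full pipeline on an emitted dataset directory; returns the report."""
    dataset, outdir = Path(dataset), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_model = build_preset(cfg.truth_model_id)
    obs_by_subject = sio.read_observations_csv(dataset / "postures.csv", truth_model)
    cohort = [
        SubjectData(subject=_StubSubject(sid), truth_model=truth_model, observations=obs)
        for sid, obs in sorted(obs_by_subject.items())
    ]
    result = run_cohort(cohort, cfg.models, cfg.train_fraction, cfg.seed)
    for f in result.fits:
        sio.write_sesc_vector_csv(
            outdir / f"sesc_{f.subject_id}_model_{f.model_id}.csv",
            build_preset(f.model_id),
            f.identification.vector,
        )
    report = build_report(result, cfg)
    sio.write_report_json(outdir / "report.json", report)
    return report


@dataclass
class _StubSubject:
    """Subject known only by id (real datasets carry no ground truth)."""

    subject_id: str


def build_report(result: CohortResult, cfg: sio.RunConfig) -> dict:
    comparison = result.comparison() if len(cfg.models) >= 2 else None
    report: dict = {"provenance": cfg.provenance(), "models": {}}
    for mid in cfg.models:
        mfits = [f for f in result.fits if f.model_id == mid]
        ba = {ax: bland_altman(result.paired[mid][ax]).report() for ax in ("AP", "ML")}
        rms3d = [f.holdout_rms_3d_mm for f in mfits]
        report["models"][mid] = {
            "holdout_rms_ap_mm_mean": float(np.mean([f.holdout_rms_ap_mm for f in mfits])),
            "holdout_rms_ml_mm_mean": float(np.mean([f.holdout_rms_ml_mm for f in mfits])),
            "holdout_rms_3d_mm_mean": (
                float(np.mean(rms3d)) if all(v is not None for v in rms3d) else None
            ),
            "bland_altman": ba,
            "identification": [f.identification.report() for f in mfits],
        }
    if comparison is not None:
        report["comparison_table"] = comparison.table.reset_index().to_dict("records")
        report["pairwise_rms_diff"] = (
            comparison.pairwise_rms_diff.reset_index().to_dict("records")
        )
    return report


def complexity_replicates(
    n_replicates: int = 20,
    config: Optional[CohortConfig] = None,
    model_ids: Sequence[str] = ("a", "d"),
    seed: int = 0,
    axis: str = "AP",
) -> dict:
    """Replicate the cohort study and compare model RMS across replicates.

    Returns per-replicate cohort-mean held-out RMS per model and the
    fraction of replicates in which the first model's error exceeds the
    last model's (the model-complexity ordering).
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(seed)
    means: Dict[str, List[float]] = {m: [] for m in model_ids}
    for r in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(cfg, rep_seed)
        res = run_cohort(cohort, model_ids, cfg.train_fraction, seed=rep_seed)
        for m in model_ids:
            means[m].append(res.cohort_mean_rms(m, axis))
    first, last = model_ids[0], model_ids[-1]
    worse = [a > d for a, d in zip(means[first], means[last])]
    return {
        "axis": axis,
        "replicates": n_replicates,
        "cohort_mean_rms_mm": {m: list(v) for m, v in means.items()},
        "fraction_first_worse_than_last": float(np.mean(worse)),
    }
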