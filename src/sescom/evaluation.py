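"""Agreement evaluation of CoM estimates against a reference.

Per axis (AP, ML): root-mean-square error, Pearson/Spearman
correlations, and Bland-Altman analysis — fixed bias (mean difference),
95% limits of agreement (bias +/- 1.96 SD of differences), and
proportional bias from a regression of the difference on the pairwise
mean.  Proportional bias is reported both pooled (OLS across all
points) and per subject: the mean and between-subject SD of per-subject
slopes form a two-stage, random-intercept-style summary; a full
likelihood-based mixed model is deliberately out of scope and the
report says so.

A telling degeneracy: an estimator whose output is constant within each
subject (a hinge-only sagittal body on the ML axis) produces
differences d = 2c - 2m against its reference, so every per-subject
Bland-Altman slope is exactly -2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "CorrelationResult",
    "BlandAltmanResult",
    "ModelComparison",
    "rms_error",
    "correlations",
    "bland_altman",
    "compare_models",
]

LOA_MULTIPLIER = 1.96  # 95% of differences under normality


@dataclass
class PairedSeries:
    """Estimate/reference pairs (mm) with subject labels, one axis."""

    estimate: np.ndarray
    reference: np.ndarray
    subject: np.ndarray  # str labels, same length
    axis: str = "AP"

    def __post_init__(self):
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.subject = np.asarray(self.subject)
        if not (len(self.estimate) == len(self.reference) == len(self.subject)):
            raise ValueError("estimate, reference and subject must have equal length")
        if not (np.all(np.isfinite(self.estimate)) and np.all(np.isfinite(self.reference))):
            raise ValueError("non-finite values in paired series")

    def __len__(self) -> int:
        return len(self.estimate)


def rms_error(pairs: PairedSeries) -> float:
    """Root-mean-square difference (mm)."""
    if len(pairs) == 0:
        raise ValueError("empty paired series")
    d = pairs.estimate - pairs.reference
    return float(np.sqrt(np.mean(d**2)))


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def correlations(pairs: PairedSeries) -> CorrelationResult:
    """Pearson r and Spearman rho with two-sided p-values."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for correlation")
    if np.std(pairs.estimate) == 0 or np.std(pairs.reference) == 0:
        raise ValueError("correlation undefined: zero variance in one series")
    pr = stats.pearsonr(pairs.estimate, pairs.reference)
    sr = stats.spearmanr(pairs.estimate, pairs.reference)
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )


@dataclass
class BlandAltmanResult:
    """Fixed bias, limits of agreement and proportional-bias regression."""

    bias_mm: float
    loa_lower_mm: float
    loa_upper_mm: float
    slope: float
    intercept_mm: float
    r_squared: float
    p_value: float
    per_subject_slopes: Dict[str, float] = field(default_factory=dict)
    subject_slope_mean: float = float("nan")
    subject_slope_sd: float = float("nan")

    def report(self) -> dict:
        return {
            "mean_difference_mm": self.bias_mm,
            "loa_lower_mm": self.loa_lower_mm,
            "loa_upper_mm": self.loa_upper_mm,
            "regression_slope": self.slope,
            "regression_intercept_mm": self.intercept_mm,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "per_subject_slopes": dict(self.per_subject_slopes),
            "subject_slope_mean": self.subject_slope_mean,
            "subject_slope_sd": self.subject_slope_sd,
            "note": (
                "proportional bias summarized as pooled OLS plus per-subject "
                "slopes (two-stage); not a likelihood-based mixed model"
            ),
        }


def _regress(d: np.ndarray, m: np.ndarray):
    """OLS of difference on mean, robust to degenerate inputs."""
    if np.ptp(m) == 0:  # all means identical: no trend estimable
        return 0.0, float(np.mean(d)), 0.0, 1.0
    if np.ptp(d) == 0:  # constant difference: flat line, no trend
        return 0.0, float(d[0]), 0.0, 1.0
    res = stats.linregress(m, d)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def bland_altman(pairs: PairedSeries) -> BlandAltmanResult:
    """Bland-Altman agreement of estimate against reference."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for Bland-Altman analysis")
    d = pairs.estimate - pairs.reference
    m = (pairs.estimate + pairs.reference) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    slope, intercept, r2, p = _regress(d, m)

    per_subject: Dict[str, float] = {}
    for s in np.unique(pairs.subject):
        mask = pairs.subject == s
        if mask.sum() >= 2 and np.ptp(m[mask]) > 0:
            coef = np.polyfit(m[mask], d[mask], 1)
            per_subject[str(s)] = float(coef[0])
    slopes = np.array(list(per_subject.values()))
    return BlandAltmanResult(
        bias_mm=bias,
        loa_lower_mm=bias - LOA_MULTIPLIER * sd,
        loa_upper_mm=bias + LOA_MULTIPLIER * sd,
        slope=slope,
        intercept_mm=intercept,
        r_squared=r2,
        p_value=p,
        per_subject_slopes=per_subject,
        subject_slope_mean=float(np.mean(slopes)) if slopes.size else float("nan"),
        subject_slope_sd=float(np.std(slopes, ddof=1)) if slopes.size > 1 else float("nan"),
    )


@dataclass
class ModelComparison:
    """Cross-model summary: one row per model x axis, plus pairwise RMS
    differences with per-subject pairing preserved."""

    table: pd.DataFrame
    per_subject_rms: pd.DataFrame  # rows: subject, cols: (model, axis)
    pairwise_rms_diff: pd.DataFrame  # rows: (model_i, model_j, axis)


def _subject_rms(pairs: PairedSeries) -> Dict[str, float]:
    out = {}
    for s in np.unique(pairs.subject):
        mask = pairs.subject == s
        d = pairs.estimate[mask] - pairs.reference[mask]
        out[str(s)] = float(np.sqrt(np.mean(d**2)))
    return out


def compare_models(
    per_model: Mapping[str, Mapping[str, PairedSeries]]
) -> ModelComparison:
    """Compare >= 2 models evaluated on identical posture sets.

    ``per_model[model_id][axis]`` holds the pooled paired series of that
    model on that axis.  References and subject labels must match across
    models exactly (same held-out postures).
    """
    if len(per_model) < 2:
        raise ValueError("need at least two models to compare")
    model_ids = list(per_model)
    axes = list(per_model[model_ids[0]])
    ref0 = {ax: per_model[model_ids[0]][ax] for ax in axes}
    for mid in model_ids[1:]:
        for ax in axes:
            p = per_model[mid][ax]
            if len(p) != len(ref0[ax]) or not np.allclose(
                p.reference, ref0[ax].reference
            ) or not np.array_equal(p.subject, ref0[ax].subject):
                raise ValueError(
                    f"model {mid!r} axis {ax!r}: posture set does not match"
                )

    rows = []
    srms_cols = {}
    for mid in model_ids:
        for ax in axes:
            pairs = per_model[mid][ax]
            srms = _subject_rms(pairs)
            srms_cols[(mid, ax)] = srms
            vals = np.array(list(srms.values()))
            ba = bland_altman(pairs)
            try:
                corr = correlations(pairs)
                r, rho = corr.pearson_r, corr.spearman_rho
            except ValueError:
                r, rho = float("nan"), float("nan")
            rows.append(
                {
                    "model": mid,
                    "axis": ax,
                    "rms_mean_mm": float(vals.mean()),
                    "rms_sd_mm": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    "rms_p25_mm": float(np.percentile(vals, 25)),
                    "rms_p75_mm": float(np.percentile(vals, 75)),
                    "pearson_r": r,
                    "spearman_rho": rho,
                    "bias_mm": ba.bias_mm,
                    "loa_lower_mm": ba.loa_lower_mm,
                    "loa_upper_mm": ba.loa_upper_mm,
                    "ba_slope": ba.slope,
                    "n_subjects": vals.size,
                }
            )
    table = pd.DataFrame(rows).set_index(["model", "axis"])
    per_subject_rms = pd.DataFrame(srms_cols)

    pw_rows = []
    for i, mi in enumerate(model_ids):
        for mj in model_ids[i + 1 :]:
            for ax in axes:
                diff = per_subject_rms[(mi, ax)] - per_subject_rms[(mj, ax)]
                pw_rows.append(
                    {
                        "model_i": mi,
                        "model_j": mj,
                        "axis": ax,
                        "mean_rms_diff_mm": float(diff.mean()),
                        "sd_rms_diff_mm": float(diff.std(ddof=1))
                        if len(diff) > 1
                        else float("nan"),
                    }
                )
    pairwise = pd.DataFrame(pw_rows).set_index(["model_i", "model_j", "axis"])
    return ModelComparison(table, per_subject_rms, pairwise)
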