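"""Raw time series -> static-posture observations.

Pipeline order follows standard identification practice: low-pass
filter the force-plate signal (4th-order Butterworth, 10 Hz cutoff,
applied forward and backward so the net phase is zero), resample to the
mocap rate (60 Hz), re-express the CoP in the body-rooted frame with
the L5 segment at the origin, detect static windows, and split postures
into identification and test sets.

A posture is deemed static when, within a 1 s window, every joint-angle
channel has SD below 1.5 deg and each CoP channel SD is below 6 mm
(per-axis reading of the displacement criterion); overlapping passing
windows are merged, and merged runs shorter than the 5 s minimum hold
are discarded.  One posture is emitted per run as the channel means
over the run's central 1 s window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TimeSeries",
    "StaticWindow",
    "lowpass_filter",
    "resample",
    "unify_frames",
    "detect_static",
    "split_postures",
]


@dataclass
class TimeSeries:
    """Uniformly sampled, named channels.

    Units follow the file-boundary convention: joint angles in degrees
    (channel ``<joint>_<axis>``), CoP and positions in millimeters.
    """

    rate_hz: float
    data: pd.DataFrame  # one column per channel

    def __post_init__(self):
        if not self.rate_hz > 0:
            raise ValueError("sample rate must be positive")
        if self.data.columns.duplicated().any():
            raise ValueError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def channels(self) -> List[str]:
        return list(self.data.columns)


def lowpass_filter(series: TimeSeries, order: int = 4, cutoff_hz: float = 10.0) -> TimeSeries:
    """Zero-phase Butterworth low-pass (forward-backward), DC gain 1."""
    nyq = series.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=series.rate_hz, output="sos")
    filtered = {
        c: signal.sosfiltfilt(sos, series.data[c].to_numpy()) for c in series.data
    }
    return TimeSeries(series.rate_hz, pd.DataFrame(filtered))


def resample(series: TimeSeries, target_hz: float = 60.0) -> TimeSeries:
    """Band-limited (polyphase) downsampling to the mocap rate."""
    if target_hz > series.rate_hz:
        raise ValueError(
            f"upsampling {series.rate_hz} -> {target_hz} Hz is out of scope"
        )
    if target_hz == series.rate_hz:
        return TimeSeries(series.rate_hz, series.data.copy())
    frac = Fraction(target_hz / series.rate_hz).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = {
        c: signal.resample_poly(series.data[c].to_numpy(), up, down, padtype="line")
        for c in series.data
    }
    return TimeSeries(target_hz, pd.DataFrame(out))


def unify_frames(
    angle_series: TimeSeries,
    cop_series: TimeSeries,
    l5_position_series: TimeSeries,
) -> TimeSeries:
    """Merge channels into the body-rooted frame (L5 at the origin).

    CoP channels (``cop_x``, ``cop_y``, mm) are shifted by the matching
    L5 horizontal position (``l5_x``, ``l5_y``, mm); all inputs must be
    at a common rate (resample first) with overlapping support.
    """
    if not (angle_series.rate_hz == cop_series.rate_hz == l5_position_series.rate_hz):
        raise ValueError("all series must share one rate; resample before unifying")
    n = min(angle_series.n_samples, cop_series.n_samples, l5_position_series.n_samples)
    if n == 0:
        raise ValueError("series have no temporal overlap")
    merged = {c: angle_series.data[c].to_numpy()[:n] for c in angle_series.data}
    for ax in ("x", "y"):
        merged[f"cop_{ax}"] = (
            cop_series.data[f"cop_{ax}"].to_numpy()[:n]
            - l5_position_series.data[f"l5_{ax}"].to_numpy()[:n]
        )
    return TimeSeries(angle_series.rate_hz, pd.DataFrame(merged))


@dataclass
class StaticWindow:
    """One accepted static hold."""

    start_s: float
    end_s: float
    means: Dict[str, float]
    sds: Dict[str, float]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _split_channels(
    series: TimeSeries,
    angle_channels: Optional[Sequence[str]],
    cop_channels: Optional[Sequence[str]],
) -> Tuple[List[str], List[str]]:
    if cop_channels is None:
        cop_channels = [c for c in series.data.columns if c.startswith("cop")]
    if angle_channels is None:
        angle_channels = [c for c in series.data.columns if c not in set(cop_channels)]
    if not cop_channels or not angle_channels:
        raise ValueError("series must contain both angle and CoP channels")
    return list(angle_channels), list(cop_channels)


def detect_static(
    series: TimeSeries,
    window_s: float = 1.0,
    angle_sd_max_deg: float = 1.5,
    cop_sd_max_mm: float = 6.0,
    min_hold_s: float = 5.0,
    angle_channels: Optional[Sequence[str]] = None,
    cop_channels: Optional[Sequence[str]] = None,
) -> List[StaticWindow]:
    """Sliding-window static detection (stride one sample).

    Returns one ``StaticWindow`` per merged run of passing windows that
    lasts at least ``min_hold_s``; its means/SDs are taken over the
    run's central ``window_s`` stretch.
    """
    angle_ch, cop_ch = _split_channels(series, angle_channels, cop_channels)
    w = int(round(window_s * series.rate_hz))
    if w < 2 or series.n_samples < w:
        return []
    roll = series.data.rolling(window=w)
    sds = roll.std(ddof=0).to_numpy()[w - 1 :]  # row i -> window starting at i
    passing = np.ones(sds.shape[0], dtype=bool)
    cols = list(series.data.columns)
    for ci, c in enumerate(cols):
        if c in angle_ch:
            passing &= sds[:, ci] < angle_sd_max_deg
        elif c in cop_ch:
            passing &= sds[:, ci] < cop_sd_max_mm

    out: List[StaticWindow] = []
    i = 0
    n_win = passing.size
    while i < n_win:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and passing[j + 1]:
            j += 1
        first, last = i, j + w  # sample span [first, last)
        duration = (last - first) / series.rate_hz
        if duration >= min_hold_s:
            center = (first + last) // 2
            lo = max(first, center - w // 2)
            hi = lo + w
            block = series.data.iloc[lo:hi]
            out.append(
                StaticWindow(
                    start_s=first / series.rate_hz,
                    end_s=last / series.rate_hz,
                    means={c: float(block[c].mean()) for c in cols},
                    sds={c: float(block[c].std(ddof=0)) for c in cols},
                )
            )
        i = j + 1
    return out


def split_postures(
    postures: Sequence,
    train_fraction: float = 0.75,
    seed: Union[int, np.random.Generator, None] = 0,
    chronological: bool = False,
    min_train: Optional[int] = None,
) -> Tuple[list, list]:
    """Partition postures into identification (train) and test sets.

    Train size is ``round(train_fraction * k)`` (half-up); the split is
    a seeded random partition by default, chronological on request.
    Warns when the train set falls below an identifiability minimum
    (pass ``min_train=sesc.min_postures(model)``).
    """
    k = len(postures)
    if k < 2:
        raise ValueError("need at least 2 postures to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(np.floor(train_fraction * k + 0.5))
    n_train = min(max(n_train, 1), k - 1)
    if chronological:
        order = np.arange(k)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order = rng.permutation(k)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    if min_train is not None and n_train < min_train:
        warnings.warn(
            f"train set of {n_train} postures is below the identification "
            f"minimum {min_train}",
            RuntimeWarning,
            stacklevel=2,
        )
    pick = lambda idx: [postures[i] for i in idx]
    return pick(train_idx), pick(test_idx)
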