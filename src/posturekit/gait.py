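"""Gait analysis from the bilateral waist channels and the chest lean angle.

Step detection band-passes the vertical-axis acceleration of each waist
channel at typical step frequencies (0.5–3 Hz) and picks peaks above an
adaptive (median + 3·MAD) threshold with a 250 ms refractory period.  The
step-symmetry index (SI) compares the alternating step intervals — the time
from a right footfall to the next left footfall ("left interval") and vice
versa:

    SI = |mean left interval − mean right interval|
         / (0.5 · (mean left + mean right)) × 100 %

0 % is a perfectly symmetric gait.  A walk summary combines the step count,
walking time, SI and the mean forward-lean angle of the chest over detected
walking intervals; summaries carrying dates aggregate into the long-term
(monthly) trend series used to watch for festination gait.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cordic import tilt_stream
from .sensor import Placement, Recording, SensorSpec

__all__ = [
    "StepSeries",
    "GaitSummary",
    "TrendSeries",
    "InsufficientStepsError",
    "detect_steps",
    "step_symmetry_index",
    "alternating_intervals",
    "walking_intervals",
    "walk_summary",
    "aggregate_trend",
]


class InsufficientStepsError(ValueError):
    """Raised when a statistic needs more steps per side than were detected."""


@dataclass
class StepSeries:
    """Detected (or ground-truth) footfall times per side, seconds."""

    left_step_times: np.ndarray
    right_step_times: np.ndarray

    def __post_init__(self) -> None:
        self.left_step_times = np.asarray(self.left_step_times, dtype=float)
        self.right_step_times = np.asarray(self.right_step_times, dtype=float)
        for name, arr in (("left", self.left_step_times),
                          ("right", self.right_step_times)):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} step times must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return int(self.left_step_times.size + self.right_step_times.size)

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All steps sorted by time, with a parallel side array ('L'/'R')."""
        t = np.r_[self.left_step_times, self.right_step_times]
        side = np.r_[np.full(self.left_step_times.size, "L"),
                     np.full(self.right_step_times.size, "R")]
        order = np.argsort(t, kind="stable")
        return t[order], side[order]


@dataclass
class GaitSummary:
    """Derived gait parameters for one recording."""

    n_steps: int
    walk_time: float
    symmetry_index: float | None
    mean_forward_lean: float | None
    sd_symmetry: float | None = None
    date: date | None = None

    def to_dict(self) -> dict:
        d = {
            "n_steps": self.n_steps,
            "walk_time": self.walk_time,
            "symmetry_index": self.symmetry_index,
            "mean_forward_lean": self.mean_forward_lean,
            "sd_symmetry": self.sd_symmetry,
        }
        if self.date is not None:
            d["date"] = self.date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaitSummary":
        dt = date.fromisoformat(d["date"]) if d.get("date") else None
        return cls(int(d["n_steps"]), float(d["walk_time"]),
                   d.get("symmetry_index"), d.get("mean_forward_lean"),
                   d.get("sd_symmetry"), dt)


@dataclass
class TrendSeries:
    """Per-period gait trend: mean/sd symmetry and mean lean angle.

    ``table`` has one row per period (periods with no data present but
    empty), columns: period, n, mean_symmetry, sd_symmetry, mean_lean.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Step detection


def _side_steps(t: np.ndarray, counts: np.ndarray, spec: SensorSpec,
                min_peak_g: float = 0.05, refractory_s: float = 0.25,
                mad_window_s: float = 5.0) -> np.ndarray:
    """Peak-picked footfall times from one waist channel."""
    fs = spec.sample_rate_hz
    if t.size < int(2 * fs):
        return np.array([])
    vert = counts[:, 2].astype(float) * spec.lsb_g
    sos = sps.butter(2, [0.5, 3.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, vert)
    s = pd.Series(filt)
    w = max(3, int(mad_window_s * fs))
    med = s.rolling(w, center=True, min_periods=1).median()
    mad = (s - med).abs().rolling(w, center=True, min_periods=1).median()
    thresh = np.maximum(med + 3.0 * mad, min_peak_g)
    peaks, _ = sps.find_peaks(filt, distance=max(1, int(refractory_s * fs)))
    peaks = peaks[filt[peaks] > thresh.to_numpy()[peaks]]
    return t[peaks]


def detect_steps(recording: Recording, min_peak_g: float = 0.05) -> StepSeries:
    """Detect footfalls on both waist channels of a recording."""
    for p in (Placement.WAIST_LEFT, Placement.WAIST_RIGHT):
        if p not in recording.channels:
            raise KeyError(f"recording is missing channel {p.value}")
    left = _side_steps(recording.t, recording.channels[Placement.WAIST_LEFT],
                       recording.spec, min_peak_g)
    right = _side_steps(recording.t, recording.channels[Placement.WAIST_RIGHT],
                        recording.spec, min_peak_g)
    return StepSeries(left, right)


# ---------------------------------------------------------------------------
# Symmetry index


def alternating_intervals(series: StepSeries) -> tuple[np.ndarray, np.ndarray]:
    """Left and right step intervals from the merged alternating sequence.

    A "left interval" is the time from a right footfall to the next left
    footfall; same-side repeats (a missed contralateral step) contribute no
    interval.
    """
    t, side = series.merged()
    left, right = [], []
    for i in range(1, t.size):
        if side[i] == side[i - 1]:
            continue
        (left if side[i] == "L" else right).append(t[i] - t[i - 1])
    return np.asarray(left), np.asarray(right)


def step_symmetry_index(series: StepSeries) -> float:
    """Interval-based step-symmetry index in percent (0 = symmetric)."""
    if series.left_step_times.size < 3 or series.right_step_times.size < 3:
        raise InsufficientStepsError("need at least 3 steps per side for SI")
    li, ri = alternating_intervals(series)
    if li.size == 0 or ri.size == 0:
        raise InsufficientStepsError("no alternating step pairs found")
    ml, mr = float(li.mean()), float(ri.mean())
    return abs(ml - mr) / (0.5 * (ml + mr)) * 100.0


def _cycle_si_sd(series: StepSeries) -> float | None:
    """Sample sd of the per-cycle instantaneous SI, percent."""
    t, side = series.merged()
    vals = []
    for i in range(2, t.size):
        if side[i] != side[i - 1] and side[i - 1] != side[i - 2]:
            a = t[i] - t[i - 1]
            b = t[i - 1] - t[i - 2]
            vals.append(abs(a - b) / (0.5 * (a + b)) * 100.0)
    if len(vals) < 2:
        return None
    return float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# Walking intervals and summary


def walking_intervals(series: StepSeries, max_gap_s: float = 2.0,
                      min_steps: int = 4) -> list[tuple[float, float]]:
    """Spans of sustained walking: runs of ≥ ``min_steps`` alternating steps
    with inter-step gaps below ``max_gap_s``."""
    t, side = series.merged()
    spans = []
    i = 0
    while i < t.size:
        j = i
        while (j + 1 < t.size and t[j + 1] - t[j] < max_gap_s
               and side[j + 1] != side[j]):
            j += 1
        if j - i + 1 >= min_steps:
            gaps = np.diff(t[i:j + 1])
            pad = float(gaps.mean() / 2) if gaps.size else 0.0
            spans.append((float(t[i]) - pad, float(t[j]) + pad))
        i = j + 1
    return spans


def walk_summary(recording: Recording, n_iter: int = 16,
                 summary_date: date | None = None) -> GaitSummary:
    """Full gait summary: steps, walking time, SI and chest forward lean.

    The forward lean is the mean CORDIC chest pitch over detected walking
    intervals only; without any walking interval it is reported as absent
    (None), as is the SI when either side has fewer than 3 steps.
    """
    if Placement.CHEST not in recording.channels:
        raise KeyError(f"recording is missing channel {Placement.CHEST.value}")
    series = detect_steps(recording)
    spans = walking_intervals(series)
    walk_time = float(sum(e - s for s, e in spans))
    walk_time = min(walk_time, recording.duration)
    try:
        si = step_symmetry_index(series)
    except InsufficientStepsError:
        si = None
    lean = None
    if spans:
        chest = tilt_stream(recording.t, recording.channels[Placement.CHEST], n_iter)
        mask = np.zeros(len(chest), dtype=bool)
        for s, e in spans:
            mask |= (chest.t >= s) & (chest.t <= e)
        if mask.any():
            lean = float(chest.pitch[mask].mean())
    return GaitSummary(series.n_steps, walk_time, si, lean,
                       _cycle_si_sd(series), summary_date)


# ---------------------------------------------------------------------------
# Long-term trend


def aggregate_trend(summaries: Sequence[GaitSummary],
                    period: str = "M") -> TrendSeries:
    """Aggregate dated summaries into a per-period trend table.

    Means are plain averages over the period's summaries; sd_symmetry is the
    sample standard deviation (n−1).  Periods between the first and last
    dated summary with no data appear with n = 0 and NaN statistics.
    """
    dated = [s for s in summaries if s.date is not None]
    if not dated:
        raise ValueError("aggregation needs dated summaries")
    df = pd.DataFrame({
        "period": [pd.Period(s.date, freq=period) for s in dated],
        "symmetry_index": [s.symmetry_index for s in dated],
        "mean_forward_lean": [s.mean_forward_lean for s in dated],
    })
    g = df.groupby("period")
    agg = pd.DataFrame({
        "n": g["symmetry_index"].count(),
        "mean_symmetry": g["symmetry_index"].mean(),
        "sd_symmetry": g["symmetry_index"].std(ddof=1),
        "mean_lean": g["mean_forward_lean"].mean(),
    })
    full = pd.period_range(df["period"].min(), df["period"].max(), freq=period)
    agg = agg.reindex(full)
    agg["n"] = agg["n"].fillna(0).astype(int)
    agg = agg.reset_index(names="period")
    agg["period"] = agg["period"].astype(str)
    return TrendSeries(agg)
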