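"""Posture classification and alert-worthy event detection.

Works on CORDIC-derived tilt streams from the vest's channels.  Postures
(standing, sitting, lying, leaning forward, transition) come from the chest
inclination and pitch in 1 s sliding windows; alerts are evaluated per
sample:

- HEAD_DOWN / TRUNK_BEND: tilt past a threshold sustained for a hold time,
  with hysteresis on release (the smartphone-neck and low-back-pain
  scenarios).
- FALL: a three-stage signature — free-fall magnitude dip, impact (saturated
  or above an impact threshold), then sustained lying inclination.
- LYING_TO_SITTING: the bed-exit precursor — chest inclination leaving the
  lying band and crossing below the sitting threshold within a bounded ramp
  time.

All thresholds live in :class:`AlertRuleConfig`; the hardware's own default
angles and hold times are not published, so these defaults are explicit,
documented choices and every one is configurable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cordic import TiltStream, tilt_stream
from .sensor import Placement, Recording

__all__ = [
    "PostureState",
    "AlertKind",
    "AlertRuleConfig",
    "EventAlert",
    "classify_posture",
    "classify_stream",
    "detect_duration_warnings",
    "detect_fall",
    "detect_lying_to_sitting",
    "detect_all",
    "tilt_streams",
]


class PostureState(enum.Enum):
    STANDING = "STANDING"
    SITTING = "SITTING"
    LYING = "LYING"
    LEANING_FORWARD = "LEANING_FORWARD"
    TRANSITION = "TRANSITION"
    UNKNOWN = "UNKNOWN"


class AlertKind(enum.Enum):
    HEAD_DOWN = "HEAD_DOWN"
    TRUNK_BEND = "TRUNK_BEND"
    FALL = "FALL"
    LYING_TO_SITTING = "LYING_TO_SITTING"


@dataclass(frozen=True)
class AlertRuleConfig:
    """Thresholds for posture classification and alert generation.

    Angles in degrees, times in seconds.  Defaults: lying above 60°
    inclination; head-down warning above 30° cervical tilt held 60 s;
    trunk-bend warning above 30° chest pitch held 10 s; lying-to-sitting
    fires when chest inclination drops below 45° within 10 s of leaving the
    lying band; a fall requires < 0.5 g for ≥ 0.2 s, an impact within 1 s
    (saturation or > 1.8 g), and ≥ 5 s of lying afterwards.
    """

    lying_angle: float = 60.0
    head_down_angle: float = 30.0
    head_down_hold: float = 60.0
    trunk_bend_angle: float = 30.0
    trunk_bend_hold: float = 10.0
    lying_to_sitting_angle: float = 45.0
    lying_to_sitting_max_ramp: float = 10.0
    lying_arm_hold: float = 2.0
    free_fall_g: float = 0.5
    free_fall_min_s: float = 0.2
    impact_g: float = 1.8
    impact_require_saturation: bool = False
    impact_window_s: float = 1.0
    post_fall_hold: float = 5.0
    release_hysteresis: float = 5.0
    lean_angle: float = 10.0
    transition_range: float = 15.0
    sitting_com_pitch: float = 15.0

    def __post_init__(self) -> None:
        for name in ("lying_angle", "head_down_angle", "trunk_bend_angle",
                     "lying_to_sitting_angle", "lean_angle"):
            v = getattr(self, name)
            if not (0 < v <= 90):
                raise ValueError(f"{name} must be in (0, 90] degrees")
        for name in ("head_down_hold", "trunk_bend_hold", "post_fall_hold",
                     "lying_arm_hold", "free_fall_min_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EventAlert:
    kind: AlertKind
    start: float
    end: float
    peak_angle: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("alert must have start < end")


def tilt_streams(recording: Recording, n_iter: int = 16) -> dict[Placement, TiltStream]:
    """CORDIC tilt streams for every channel of a recording."""
    return {p: tilt_stream(recording.t, c, n_iter)
            for p, c in recording.channels.items()}


# ---------------------------------------------------------------------------
# Posture classification


def classify_posture(tilt_window: Mapping[Placement, TiltStream],
                     config: AlertRuleConfig | None = None) -> PostureState:
    """Classify one analysis window (≥ 1 s of chest tilt) into a posture.

    Rules, in priority order: UNKNOWN without a chest channel; TRANSITION if
    chest inclination sweeps more than ``transition_range`` within the
    window; LYING above the lying threshold (median); LEANING_FORWARD when
    the median chest pitch exceeds ``lean_angle``; otherwise SITTING or
    STANDING split on the COM-channel pitch — a heuristic, since trunk
    orientation alone cannot separate the two.
    """
    config = config or AlertRuleConfig()
    chest = tilt_window.get(Placement.CHEST)
    if chest is None or len(chest) == 0:
        return PostureState.UNKNOWN
    incl = chest.inclination
    if float(incl.max() - incl.min()) > config.transition_range:
        return PostureState.TRANSITION
    med_incl = float(np.median(incl))
    if med_incl > config.lying_angle:
        return PostureState.LYING
    if float(np.median(chest.pitch)) > config.lean_angle:
        return PostureState.LEANING_FORWARD
    com = tilt_window.get(Placement.COM_L3)
    if com is not None and len(com) and float(np.median(com.pitch)) > config.sitting_com_pitch:
        return PostureState.SITTING
    return PostureState.STANDING


def classify_stream(tilts: Mapping[Placement, TiltStream],
                    config: AlertRuleConfig | None = None,
                    window_s: float = 1.0, step_s: float = 0.5):
    """Sliding-window posture sequence: list of (window centre s, state)."""
    config = config or AlertRuleConfig()
    chest = tilts.get(Placement.CHEST)
    if chest is None or len(chest) == 0:
        return []
    t = chest.t
    out = []
    start = float(t[0])
    while start + window_s <= float(t[-1]) + 1e-9:
        sel = (t >= start) & (t < start + window_s)
        window = {p: TiltStream(s.t[sel], s.pitch[sel], s.roll[sel], s.inclination[sel])
                  for p, s in tilts.items()}
        out.append((start + window_s / 2, classify_posture(window, config)))
        start += step_s
    return out


# ---------------------------------------------------------------------------
# Duration warnings (head-down, trunk-bend)


def _sustained_excursions(t: np.ndarray, signal: np.ndarray, angle: float,
                          hold: float, hysteresis: float):
    """Excursions above ``angle`` (released below angle − hysteresis) that
    last at least ``hold`` seconds.  Returns (start, end, peak) triples."""
    out = []
    inside = False
    start_i = 0
    peak = -np.inf
    release = angle - hysteresis
    for i, v in enumerate(signal):
        if not inside:
            if v > angle:
                inside = True
                start_i = i
                peak = v
        else:
            if v > peak:
                peak = v
            if v < release:
                if t[i - 1] - t[start_i] >= hold:
                    out.append((float(t[start_i]), float(t[i - 1]), float(peak)))
                inside = False
    if inside and t[-1] - t[start_i] >= hold:
        out.append((float(t[start_i]), float(t[-1]), float(peak)))
    return out


def detect_duration_warnings(tilts: Mapping[Placement, TiltStream],
                             rules: AlertRuleConfig | None = None) -> list[EventAlert]:
    """HEAD_DOWN (cervical tilt) and TRUNK_BEND (chest pitch) hold warnings."""
    rules = rules or AlertRuleConfig()
    alerts: list[EventAlert] = []
    chest = tilts.get(Placement.CHEST)
    # When the wearer is lying the trunk and neck are tilted by posture, not
    # by bending; gate both warnings off inside the lying band.
    upright = None
    if chest is not None and len(chest):
        upright = chest.inclination <= rules.lying_angle
    cerv = tilts.get(Placement.CERVICAL)
    if cerv is not None and len(cerv):
        sig = cerv.inclination
        if upright is not None and len(upright) == len(sig):
            sig = np.where(upright, sig, 0.0)
        for s, e, p in _sustained_excursions(cerv.t, sig,
                                             rules.head_down_angle,
                                             rules.head_down_hold,
                                             rules.release_hysteresis):
            alerts.append(EventAlert(AlertKind.HEAD_DOWN, s, e, p))
    if chest is not None and len(chest):
        sig = np.where(upright, chest.pitch, 0.0)
        for s, e, p in _sustained_excursions(chest.t, sig,
                                             rules.trunk_bend_angle,
                                             rules.trunk_bend_hold,
                                             rules.release_hysteresis):
            alerts.append(EventAlert(AlertKind.TRUNK_BEND, s, e, p))
    return sorted(alerts, key=lambda a: (a.start, a.kind.value))


# ---------------------------------------------------------------------------
# Fall detection


def detect_fall(chest_tilt: TiltStream, com_magnitude_g: np.ndarray,
                com_saturated: np.ndarray, rules: AlertRuleConfig | None = None,
                sample_rate_hz: float = 100.0) -> list[EventAlert]:
    """Three-stage fall detector on aligned chest-tilt / COM-magnitude streams.

    Stage 1: magnitude < ``free_fall_g`` for at least ``free_fall_min_s``.
    Stage 2: within ``impact_window_s`` of the dip ending, a saturated
    sample or magnitude > ``impact_g``.  Stage 3: chest inclination above
    the lying threshold sustained for ``post_fall_hold`` starting within 3 s
    of impact.  All three stages are required.
    """
    rules = rules or AlertRuleConfig()
    t = chest_tilt.t
    n = len(t)
    if n == 0:
        return []
    dt = 1.0 / sample_rate_hz
    low = com_magnitude_g < rules.free_fall_g
    impact = com_saturated | (com_magnitude_g > rules.impact_g)
    if rules.impact_require_saturation:
        impact = np.asarray(com_saturated, dtype=bool)
    lying = chest_tilt.inclination > rules.lying_angle

    alerts: list[EventAlert] = []
    i = 0
    min_dip = max(1, int(round(rules.free_fall_min_s / dt)))
    hold_n = max(1, int(round(rules.post_fall_hold / dt)))
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        if (j - i) >= min_dip:
            k_max = min(n, j + int(round(rules.impact_window_s / dt)))
            k = next((k for k in range(j, k_max) if impact[k]), None)
            if k is not None:
                onset_max = min(n, k + int(round(3.0 / dt)))
                fired = False
                for m in range(k, onset_max):
                    if lying[m] and m + hold_n <= n and lying[m:m + hold_n].all():
                        peak = float(chest_tilt.inclination[m:m + hold_n].max())
                        alerts.append(EventAlert(AlertKind.FALL, float(t[i]),
                                                 float(t[m + hold_n - 1]), peak))
                        fired = True
                        break
                if fired:
                    i = m + hold_n
                    continue
        i = j
    return alerts


def detect_fall_recording(recording: Recording,
                          rules: AlertRuleConfig | None = None,
                          n_iter: int = 16) -> list[EventAlert]:
    """Fall detection straight from a Recording (COM magnitude + chest tilt)."""
    rules = rules or AlertRuleConfig()
    chest = tilt_stream(recording.t, recording.channels[Placement.CHEST], n_iter)
    com = recording.channels[Placement.COM_L3]
    mag = recording.magnitude_g(Placement.COM_L3)
    sat = (com >= recording.spec.count_max) | (com <= recording.spec.count_min)
    return detect_fall(chest, mag, sat.any(axis=1), rules,
                       recording.spec.sample_rate_hz)


# ---------------------------------------------------------------------------
# Lying-to-sitting transition


def detect_lying_to_sitting(chest_tilt: TiltStream,
                            rules: AlertRuleConfig | None = None) -> list[EventAlert]:
    """Detect chest inclination leaving the lying band and reaching sitting.

    The detector arms after the inclination has stayed above ``lying_angle``
    for ``lying_arm_hold`` seconds; it fires when the (lightly smoothed)
    inclination then crosses below ``lying_to_sitting_angle`` within
    ``lying_to_sitting_max_ramp`` seconds of leaving the lying band.  The
    event onset is placed where the inclination first dropped
    ``release_hysteresis`` degrees below the lying plateau, so rolling over
    in bed (inclination stays high) and sitting-to-lying (wrong direction)
    do not fire.
    """
    rules = rules or AlertRuleConfig()
    t = chest_tilt.t
    n = len(t)
    if n < 3:
        return []
    # light smoothing (~0.2 s) for plateau/onset estimation under noise
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(0.2 / dt)))
    kernel = np.ones(w) / w
    incl = np.convolve(chest_tilt.inclination, kernel, mode="same")

    alerts: list[EventAlert] = []
    armed = False
    above_since: float | None = None
    left_band_t: float | None = None
    plateau = 0.0
    for i in range(n):
        v = incl[i]
        if v > rules.lying_angle:
            if above_since is None:
                above_since = t[i]
                plateau = v
            plateau = max(plateau, v)
            if t[i] - above_since >= rules.lying_arm_hold:
                armed = True
            left_band_t = None
        else:
            if armed and left_band_t is None:
                left_band_t = t[i]
            above_since = None
            if armed and left_band_t is not None:
                if t[i] - left_band_t > rules.lying_to_sitting_max_ramp:
                    armed = False  # too slow: not a transition
                elif v < rules.lying_to_sitting_angle:
                    onset = t[i]
                    thr = plateau - rules.release_hysteresis
                    for k in range(i, -1, -1):
                        if incl[k] >= thr:
                            onset = t[k]
                            break
                    alerts.append(EventAlert(AlertKind.LYING_TO_SITTING,
                                             float(onset), float(t[i]),
                                             float(plateau)))
                    armed = False
    return alerts


def detect_all(recording: Recording, rules: AlertRuleConfig | None = None,
               n_iter: int = 16) -> list[EventAlert]:
    """Run every detector on a recording and return the merged alert list."""
    rules = rules or AlertRuleConfig()
    tilts = tilt_streams(recording, n_iter)
    alerts = detect_duration_warnings(tilts, rules)
    if Placement.CHEST in tilts and Placement.COM_L3 in recording.channels:
        alerts += detect_fall_recording(recording, rules, n_iter)
        alerts += detect_lying_to_sitting(tilts[Placement.CHEST], rules)
    return sorted(alerts, key=lambda a: (a.start, a.kind.value))
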