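"""Synthetic multichannel accelerometer recordings and the sensor front-end model.

The vest carries five 3-axis MEMS accelerometers (±2 g range, 12-bit
resolution, 100 Hz, 1 LSB = 2^-10 g ≈ 1 mg).  This module models that
digitisation (quantisation with saturation, additive Gaussian noise, per-axis
bias) and generates physically plausible recordings — static postures,
walking with controllable left/right asymmetry and forward lean, falls,
lying-to-sitting transitions, trunk bends, head-down episodes and body
turns while lying — each with ground-truth labels, so every downstream
stage can be exercised without hardware.

Body-frame convention: Z up along the spine, X anterior, Y left; a sensor on
an upright, motionless wearer reads (0, 0, +1 g).  Orientations are given as
(pitch, roll) in degrees, pitch rotating the body X axis toward gravity.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "SensorSpec",
    "Placement",
    "AccelTriplet",
    "Label",
    "Recording",
    "quantize_sample",
    "quantize",
    "dequantize",
    "gravity_in_sensor",
    "simulate_static",
    "simulate_walk",
    "simulate_event",
]


@dataclass(frozen=True)
class SensorSpec:
    """Acquisition parameters of one accelerometer channel.

    Defaults reproduce the vest's configuration: ±2 g range, 12-bit counts,
    100 Hz sampling, sensitivity of 1 count per 2^-10 g (the "1 mg" LSB).
    """

    range_g: float = 2.0
    resolution_bits: int = 12
    sample_rate_hz: float = 100.0
    lsb_g: float = 2.0 ** -10
    noise_sd_g: float = 0.005
    bias_g: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.sample_rate_hz > 0):
            raise ValueError("sample_rate_hz must be positive")
        if not (8 <= self.resolution_bits <= 16):
            raise ValueError("resolution_bits must be in [8, 16]")
        if not (self.range_g > 0 and self.lsb_g > 0):
            raise ValueError("range_g and lsb_g must be positive")
        if len(self.bias_g) != 3:
            raise ValueError("bias_g must have one entry per axis")

    @property
    def count_min(self) -> int:
        return -(1 << (self.resolution_bits - 1))

    @property
    def count_max(self) -> int:
        return (1 << (self.resolution_bits - 1)) - 1


class Placement(enum.Enum):
    """The five sensor locations on the vest, in acquisition channel order."""

    CERVICAL = "CERVICAL"        # lower cervical spine: neck/upper-back bending
    CHEST = "CHEST"              # mid-chest: trunk posture and lean
    COM_L3 = "COM_L3"            # lumbar L3, centre of mass: balance/stability
    WAIST_RIGHT = "WAIST_RIGHT"  # right waist: right-side step impacts
    WAIST_LEFT = "WAIST_LEFT"    # left waist: left-side step impacts

    @property
    def channel(self) -> int:
        """1-based acquisition channel id (enable line number)."""
        return list(Placement).index(self) + 1


def default_mounting() -> dict[Placement, np.ndarray]:
    """Mounting rotation (body frame -> sensor frame) per placement.

    The vest's true mounting orientations are not specified; identity is the
    default and callers may substitute any proper rotation matrices.
    """
    return {p: np.eye(3) for p in Placement}


class AccelTriplet(NamedTuple):
    """One 3-axis sample in signed integer counts, with its timestamp."""

    ax: int
    ay: int
    az: int
    t: float

    def magnitude_g(self, spec: SensorSpec) -> float:
        return math.sqrt(self.ax ** 2 + self.ay ** 2 + self.az ** 2) * spec.lsb_g


class Label(NamedTuple):
    """Ground-truth annotation: [start, end] seconds and an event kind string.

    Point events (single step footfalls) use start == end.
    """

    start: float
    end: float
    kind: str


@dataclass
class Recording:
    """Time-aligned multichannel count streams plus optional ground truth.

    ``channels`` maps each placement to an (n, 3) int array of counts sharing
    the timestamp vector ``t``.
    """

    spec: SensorSpec
    t: np.ndarray
    channels: dict[Placement, np.ndarray]
    labels: list[Label] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.shape[0]
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            expected = 1.0 / self.spec.sample_rate_hz
            # tolerance admits timestamps serialised at 4 decimal places
            if not np.allclose(dt, expected, rtol=0, atol=max(expected * 1e-3, 2e-4)):
                raise ValueError("timestamps must be uniformly spaced at the sample rate")
        for p, c in self.channels.items():
            c = np.asarray(c)
            if c.shape != (n, 3):
                raise ValueError(f"channel {p.value} shape {c.shape} != ({n}, 3)")
            if not np.issubdtype(c.dtype, np.integer):
                raise ValueError(f"channel {p.value} must hold integer counts")
            self.channels[p] = c.astype(np.int64)

    @property
    def duration(self) -> float:
        if self.t.size == 0:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.spec.sample_rate_hz

    def magnitude_g(self, placement: Placement) -> np.ndarray:
        """Per-sample signal magnitude sqrt(Ax²+Ay²+Az²) in gravity units."""
        c = self.channels[placement].astype(float)
        return np.sqrt((c ** 2).sum(axis=1)) * self.spec.lsb_g

    def samples(self, placement: Placement) -> list[AccelTriplet]:
        c = self.channels[placement]
        return [AccelTriplet(int(a), int(b), int(d), float(tt))
                for (a, b, d), tt in zip(c, self.t)]

    def labels_of(self, kind: str) -> list[Label]:
        return [l for l in self.labels if l.kind.split()[0] == kind]


# ---------------------------------------------------------------------------
# Quantisation


def quantize(accel_g: np.ndarray, spec: SensorSpec | None = None) -> np.ndarray:
    """Digitise accelerations in g to signed integer counts.

    Round-to-nearest at one LSB (2^-10 g by default), saturating at the
    representable 12-bit bounds.  The mapping is monotone and odd-symmetric
    up to saturation.
    """
    spec = spec or SensorSpec()
    a = np.asarray(accel_g, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("acceleration input contains non-finite values")
    counts = np.rint(a / spec.lsb_g)
    counts = np.clip(counts, spec.count_min, spec.count_max)
    return counts.astype(np.int64)


def quantize_sample(accel_g: Sequence[float], spec: SensorSpec | None = None,
                    t: float = 0.0) -> AccelTriplet:
    """Quantise a single (ax, ay, az) gravity-unit sample to an AccelTriplet."""
    c = quantize(np.asarray(accel_g, dtype=float).reshape(3), spec)
    return AccelTriplet(int(c[0]), int(c[1]), int(c[2]), t)


def dequantize(counts: np.ndarray, spec: SensorSpec | None = None) -> np.ndarray:
    """Convert integer counts back to gravity units (centre of each code bin)."""
    spec = spec or SensorSpec()
    return np.asarray(counts, dtype=float) * spec.lsb_g


# ---------------------------------------------------------------------------
# Orientation model


def gravity_in_sensor(pitch_deg, roll_deg):
    """Gravity vector seen by a sensor at the given (pitch, roll), in g.

    pitch rotates body X toward gravity, roll rotates about X; upright
    (0°, 0°) reads (0, 0, 1).  Accepts scalars or arrays (broadcast).
    Inclination of the result is arccos(cos(pitch)·cos(roll)).
    """
    p = np.radians(pitch_deg)
    r = np.radians(roll_deg)
    ax = np.sin(p)
    ay = np.sin(r) * np.cos(p)
    az = np.cos(r) * np.cos(p)
    return np.stack(np.broadcast_arrays(ax, ay, az), axis=-1)


def _times(duration_s: float, spec: SensorSpec) -> np.ndarray:
    n = int(round(duration_s * spec.sample_rate_hz))
    return np.arange(n) / spec.sample_rate_hz


def _digitise(accel_g: np.ndarray, spec: SensorSpec, rng: np.random.Generator) -> np.ndarray:
    noisy = accel_g + np.asarray(spec.bias_g)
    if spec.noise_sd_g > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sd_g, size=accel_g.shape)
    return quantize(noisy, spec)


# ---------------------------------------------------------------------------
# Simulators


def simulate_static(pitch_deg: float, roll_deg: float, duration_s: float,
                    spec: SensorSpec | None = None, seed: int = 0) -> Recording:
    """Static posture: the gravity vector in the sensor frame plus noise.

    All five channels see the same rigid-body orientation (identity
    mounting).  Ground truth is recorded as a ``static`` label spanning the
    recording.
    """
    spec = spec or SensorSpec()
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    rng = np.random.default_rng(seed)
    t = _times(duration_s, spec)
    g = gravity_in_sensor(pitch_deg, roll_deg) * np.ones((t.size, 1))
    channels = {p: _digitise(g, spec, rng) for p in Placement}
    labels = [Label(0.0, float(t[-1]), f"static pitch={pitch_deg:g} roll={roll_deg:g}")]
    return Recording(spec, t, channels, labels, seed)


def _raised_cosine_bumps(t: np.ndarray, centres: np.ndarray,
                         amplitude_g: float, width_s: float) -> np.ndarray:
    out = np.zeros_like(t)
    half = width_s / 2.0
    for c in centres:
        m = np.abs(t - c) < half
        out[m] += amplitude_g * 0.5 * (1.0 + np.cos(np.pi * (t[m] - c) / half))
    return out


def simulate_walk(cadence_spm: float, duration_s: float, asymmetry: float = 0.0,
                  lean_deg: float = 0.0, spec: SensorSpec | None = None,
                  seed: int = 0, step_jitter_s: float = 0.01,
                  bump_amplitude_g: float = 0.5, bump_width_s: float = 0.25,
                  lean_osc_deg: float = 2.0) -> Recording:
    """Walking: alternating per-side step impulses plus a forward trunk lean.

    ``cadence_spm`` is the total step rate (both feet).  ``asymmetry`` a in
    [0, 0.5) skews the alternating step intervals so that the injected
    interval-based step-symmetry index is 100·a percent: with stride time
    T_c, the right→left interval is T_c·(2+a)/4 and left→right is
    T_c·(2−a)/4.  The chest channel carries a constant forward-lean pitch of
    ``lean_deg`` with a small gait oscillation.  True footfall times are
    stored as point labels ``step_left`` / ``step_right``; the walking span
    as ``walking``.
    """
    spec = spec or SensorSpec()
    if not (40 <= cadence_spm <= 200):
        raise ValueError("cadence must be in [40, 200] steps/min")
    if not (0 <= asymmetry < 0.5):
        raise ValueError("asymmetry must be in [0, 0.5)")
    stride_s = 2.0 * 60.0 / cadence_spm
    i_left = stride_s * (2.0 + asymmetry) / 4.0   # right -> left footfall
    i_right = stride_s * (2.0 - asymmetry) / 4.0  # left -> right footfall
    rng = np.random.default_rng(seed)
    t = _times(duration_s, spec)

    # Alternating footfall sequence starting with a left step.
    margin = 0.5
    times, sides = [], []
    s, side = margin, "L"
    while s < duration_s - margin:
        times.append(s + (rng.normal(0.0, step_jitter_s) if step_jitter_s > 0 else 0.0))
        sides.append(side)
        s += i_right if side == "L" else i_left
        side = "R" if side == "L" else "L"
    left_times = np.array([x for x, sd in zip(times, sides) if sd == "L"])
    right_times = np.array([x for x, sd in zip(times, sides) if sd == "R"])
    if left_times.size < 2 or right_times.size < 2:
        raise ValueError("duration too short to contain at least 2 steps per side")

    upright = gravity_in_sensor(0.0, 0.0)
    step_hz = cadence_spm / 60.0

    def waist(ipsi: np.ndarray, contra: np.ndarray) -> np.ndarray:
        a = upright * np.ones((t.size, 1))
        a[:, 2] += _raised_cosine_bumps(t, ipsi, bump_amplitude_g, bump_width_s)
        a[:, 2] += _raised_cosine_bumps(t, contra, 0.25 * bump_amplitude_g, bump_width_s)
        return a

    chest_pitch = lean_deg + lean_osc_deg * np.sin(2 * np.pi * step_hz * t)
    chest = gravity_in_sensor(chest_pitch, np.zeros_like(t))
    trunk_osc = 0.5 * lean_osc_deg * np.sin(2 * np.pi * step_hz * t + 0.7)
    cervical = gravity_in_sensor(0.5 * lean_deg + trunk_osc, np.zeros_like(t))
    com = gravity_in_sensor(trunk_osc, np.zeros_like(t))
    com[:, 2] += _raised_cosine_bumps(t, np.sort(np.r_[left_times, right_times]),
                                      0.3 * bump_amplitude_g, bump_width_s)

    channels = {
        Placement.CERVICAL: _digitise(cervical, spec, rng),
        Placement.CHEST: _digitise(chest, spec, rng),
        Placement.COM_L3: _digitise(com, spec, rng),
        Placement.WAIST_RIGHT: _digitise(waist(right_times, left_times), spec, rng),
        Placement.WAIST_LEFT: _digitise(waist(left_times, right_times), spec, rng),
    }
    labels = [Label(float(x), float(x), "step_left") for x in left_times]
    labels += [Label(float(x), float(x), "step_right") for x in right_times]
    labels.append(Label(float(min(times)), float(max(times)), "walking"))
    labels.append(Label(0.0, float(t[-1]),
                        f"walk cadence={cadence_spm:g} asymmetry={asymmetry:g} lean={lean_deg:g}"))
    return Recording(spec, t, channels, labels, seed)


def _ramp(t: np.ndarray, t0: float, t1: float, v0: float, v1: float) -> np.ndarray:
    """Piecewise-linear profile: v0 before t0, linear to v1 at t1, v1 after."""
    out = np.full_like(t, v0, dtype=float)
    rising = (t >= t0) & (t < t1)
    out[rising] = v0 + (v1 - v0) * (t[rising] - t0) / (t1 - t0)
    out[t >= t1] = v1
    return out


def simulate_event(kind: str, spec: SensorSpec | None = None, seed: int = 0,
                   **params) -> Recording:
    """Scripted event kinematics with an exact ground-truth window label.

    Kinds and their parameters (seconds / degrees):

    - ``fall``: upright ``pre_s`` (2), free-fall ``freefall_s`` (0.3) at
      ~0.05 g, impact ``impact_s`` (0.08) at ``impact_g`` (4, saturating the
      ±2 g range), then lying at 85° inclination for ``lying_s`` (6).
    - ``lying_to_sitting``: lying at 85° for ``pre_s`` (3), chest inclination
      ramps to 10° over ``ramp_s`` (2), sitting hold ``post_s`` (3).
    - ``trunk_bend``: upright ``pre_s`` (2), chest pitch ramps to
      ``angle_deg`` (40) over ``ramp_s`` (1), holds ``hold_s`` (30), returns.
      The cervical channel follows at 40% of the bend (the head stays more
      level than the trunk).
    - ``head_down``: cervical tilt ramps to ``angle_deg`` (50) over
      ``ramp_s`` (1), holds ``hold_s`` (120), returns; chest stays upright.
    - ``body_turn``: lying throughout; roll sweeps from 85° to 95° over
      ``ramp_s`` (3) so inclination never leaves the lying band.
    """
    spec = spec or SensorSpec()
    rng = np.random.default_rng(seed)

    def mk(t, pitch, roll, label):
        base = {p: _digitise(gravity_in_sensor(np.zeros_like(t), np.zeros_like(t)), spec, rng)
                for p in (Placement.COM_L3, Placement.WAIST_RIGHT, Placement.WAIST_LEFT)}
        return t, base, label, pitch, roll

    if kind == "fall":
        pre = params.get("pre_s", 2.0)
        ff = params.get("freefall_s", 0.3)
        imp = params.get("impact_s", 0.08)
        lying = params.get("lying_s", 6.0)
        impact_g = params.get("impact_g", 4.0)
        t = _times(pre + ff + imp + lying, spec)
        a = np.zeros((t.size, 3))
        phase_pre = t < pre
        phase_ff = (t >= pre) & (t < pre + ff)
        phase_imp = (t >= pre + ff) & (t < pre + ff + imp)
        phase_ly = t >= pre + ff + imp
        a[phase_pre] = gravity_in_sensor(0.0, 0.0)
        a[phase_ff] = [0.0, 0.0, 0.05]           # near free-fall
        a[phase_imp] = [impact_g, 0.0, impact_g]  # saturating impact transient
        a[phase_ly] = gravity_in_sensor(85.0, 0.0)
        channels = {}
        for p in Placement:
            channels[p] = _digitise(a, spec, rng)
        labels = [Label(float(pre), float(t[-1]), "fall")]
        return Recording(spec, t, channels, labels, seed)

    if kind == "lying_to_sitting":
        pre = params.get("pre_s", 3.0)
        ramp = params.get("ramp_s", 2.0)
        post = params.get("post_s", 3.0)
        t = _times(pre + ramp + post, spec)
        pitch = _ramp(t, pre, pre + ramp, 85.0, 10.0)
        roll = np.zeros_like(t)
        label = Label(float(pre), float(pre + ramp), "lying_to_sitting")
        t, base, label, pitch, roll = mk(t, pitch, roll, label)
    elif kind == "trunk_bend":
        pre = params.get("pre_s", 2.0)
        ramp = params.get("ramp_s", 1.0)
        hold = params.get("hold_s", 30.0)
        angle = params.get("angle_deg", 40.0)
        t = _times(pre + ramp + hold + ramp + 2.0, spec)
        up = _ramp(t, pre, pre + ramp, 0.0, angle)
        down = _ramp(t, pre + ramp + hold, pre + ramp + hold + ramp, 0.0, -angle)
        pitch = up + down
        roll = np.zeros_like(t)
        label = Label(float(pre + ramp), float(pre + ramp + hold), "trunk_bend")
        t, base, label, pitch, roll = mk(t, pitch, roll, label)
    elif kind == "head_down":
        pre = params.get("pre_s", 2.0)
        ramp = params.get("ramp_s", 1.0)
        hold = params.get("hold_s", 120.0)
        angle = params.get("angle_deg", 50.0)
        t = _times(pre + ramp + hold + ramp + 2.0, spec)
        up = _ramp(t, pre, pre + ramp, 0.0, angle)
        down = _ramp(t, pre + ramp + hold, pre + ramp + hold + ramp, 0.0, -angle)
        cerv_pitch = up + down
        chest = _digitise(gravity_in_sensor(np.zeros_like(t), np.zeros_like(t)), spec, rng)
        cerv = _digitise(gravity_in_sensor(cerv_pitch, np.zeros_like(t)), spec, rng)
        _, base, _, _, _ = mk(t, None, None, None)
        channels = {Placement.CERVICAL: cerv, Placement.CHEST: chest, **base}
        labels = [Label(float(pre + ramp), float(pre + ramp + hold), "head_down")]
        return Recording(spec, t, channels, labels, seed)
    elif kind == "body_turn":
        pre = params.get("pre_s", 2.0)
        ramp = params.get("ramp_s", 3.0)
        post = params.get("post_s", 2.0)
        t = _times(pre + ramp + post, spec)
        pitch = np.zeros_like(t)
        roll = _ramp(t, pre, pre + ramp, 85.0, 95.0)
        label = Label(float(pre), float(pre + ramp), "body_turn")
        t, base, label, pitch, roll = mk(t, pitch, roll, label)
    else:
        raise ValueError(f"unknown event kind: {kind!r}")

    chest = _digitise(gravity_in_sensor(pitch, roll), spec, rng)
    cerv_factor = 0.4 if kind == "trunk_bend" else 0.2
    cerv = _digitise(gravity_in_sensor(cerv_factor * pitch, np.zeros_like(t)), spec, rng)
    channels = {Placement.CERVICAL: cerv, Placement.CHEST: chest, **base}
    return Recording(spec, t, channels, [label], seed)
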