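"""Integer-only CORDIC tilt-angle transformation.

Converts raw 3-axis accelerometer counts into pitch, roll and inclination
using only add/subtract/arithmetic-shift operations on integer state — the
same fixed-point vectoring-mode CORDIC a small microcontroller would run.
Angles are accumulated internally in signed micro-degrees (1e-6 degree)
with one extra guard bit on the accumulator, and converted to floating
degrees only at the API boundary.

Vectoring mode rotates a 2-D integer vector (x, y), x > 0, onto the +x axis
through the fixed micro-rotation schedule arctan(2^-i), i = 0..n-1, with the
per-iteration decision d_i = -sign(y_i) (sign(0) = +1):

    x_{i+1} = x_i - d_i * (y_i >> i)
    y_{i+1} = y_i + d_i * (x_i >> i)
    z_{i+1} = z_i - d_i * atan(2^-i)

On exit z ≈ atan2(y, x) and x ≈ K_n * sqrt(x0² + y0²), where the CORDIC
gain K_n = prod_i sqrt(1 + 2^-2i) → 1.6468 is removed by a shift-add
multiplication with a precomputed Q16 reciprocal (no division, no floats).

Tilt extraction is staged: vectoring in the (Az, Ay) plane yields roll and
the Y-Z in-plane magnitude; vectoring that magnitude against Ax yields
pitch; vectoring the gain-corrected X-Y magnitude against Az yields the
inclination (angle between the sensor Z axis and gravity), with sign-swap
quadrant pre-rotation folded back afterwards so the full ranges
pitch ∈ [-90°, 90°], roll ∈ (-180°, 180°], inclination ∈ [0°, 180°] are
covered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "MICRODEG",
    "AngleLUT",
    "TiltAngles",
    "TiltStream",
    "build_atan_lut",
    "cordic_gain",
    "cordic_vectoring",
    "gain_compensate",
    "tilt_from_counts",
    "tilt_stream",
]

MICRODEG = 1_000_000          # scaled-integer angle units per degree
_GUARD = 2                    # one guard bit on the z accumulator
_RECIP_BITS = 16              # Q16 reciprocal for gain removal
_NORM_BITS = 20               # input normalisation target inside the core


@dataclass(frozen=True)
class AngleLUT:
    """Arctangent lookup table: round(atan(2^-i) * scale) for i = 0..n-1.

    ``guard_entries`` hold the same angles at twice the scale (one guard bit
    of accumulator precision); the guard bit is dropped, with rounding, when
    an accumulated angle leaves the core loop.
    """

    entries: tuple[int, ...]
    n_iter: int
    scale: int = MICRODEG
    guard_entries: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.entries) != self.n_iter:
            raise ValueError("entry count must equal n_iter")
        if any(a <= b for a, b in zip(self.entries, self.entries[1:])):
            raise ValueError("entries must be strictly decreasing")
        if self.guard_entries is None:
            object.__setattr__(self, "guard_entries",
                               tuple(_GUARD * e for e in self.entries))


def build_atan_lut(n_iter: int = 16, scale: int = MICRODEG) -> AngleLUT:
    """Build the micro-rotation angle table at the given integer scale.

    Entries are rounded to nearest; the accumulated rounding error over
    n_iter additions is at most n_iter/2 units, far below the final
    rotation step for any admissible scale.
    """
    if not (8 <= n_iter <= 24):
        raise ValueError("n_iter must be in [8, 24]")
    first = math.degrees(math.atan(1.0)) * scale
    if first > 2 ** 31 - 1:
        raise OverflowError("scale overflows 32-bit storage for the 45° entry")
    degs = [math.degrees(math.atan(2.0 ** -i)) for i in range(n_iter)]
    entries = tuple(round(d * scale) for d in degs)
    guards = tuple(round(d * scale * _GUARD) for d in degs)
    return AngleLUT(entries, n_iter, scale, guards)


def cordic_gain(n_iter: int = 16) -> float:
    """CORDIC magnitude gain K_n = prod sqrt(1 + 2^-2i)."""
    return math.prod(math.sqrt(1.0 + 4.0 ** -i) for i in range(n_iter))


def _reciprocal_q16(n_iter: int) -> int:
    return round((1.0 / cordic_gain(n_iter)) * (1 << _RECIP_BITS))


def _vectoring_arrays(x: np.ndarray, y: np.ndarray, lut: AngleLUT):
    """Vectoring loop on int64 arrays; x must be positive elementwise.

    Returns (z, mag) with z in ``lut.scale * _GUARD`` units (guard bit still
    attached) and mag = K_n * sqrt(x²+y²) (gain not removed).
    numpy's >> on int64 is an arithmetic shift, matching hardware.
    """
    # Normalise each vector into [2^NORM, 2^(NORM+1)) by a common left shift
    # (angle-invariant) so shift-truncation noise is negligible even for
    # tiny inputs; a hardware core does the same with a leading-zero count.
    x = x.astype(np.int64)
    y = y.astype(np.int64)
    m = np.maximum(np.abs(x), np.abs(y))
    exp = np.zeros_like(m)
    nz = m > 0
    # floor(log2(m)): float64 frexp is exact for these magnitudes
    exp[nz] = np.frexp(m[nz].astype(np.float64))[1] - 1
    shift = np.clip(_NORM_BITS - exp, 0, None)
    x = x << shift
    y = y << shift
    z = np.zeros_like(x)
    for i, ga in enumerate(lut.guard_entries):
        d = np.where(y < 0, np.int64(1), np.int64(-1))  # d = -sign(y), sign(0)=+1
        x, y, z = x - d * (y >> i), y + d * (x >> i), z - d * np.int64(ga)
    half = np.where(shift > 0, np.int64(1) << np.maximum(shift - 1, 0), np.int64(0))
    mag = (x + half) >> shift
    return z, mag


def cordic_vectoring(x: int, y: int, n_iter: int = 16,
                     lut: AngleLUT | None = None) -> tuple[int, int]:
    """Vectoring-mode CORDIC on one integer vector with x > 0.

    Returns ``(angle, magnitude_scaled)``: the angle atan2(y, x) in the
    LUT's scaled units (micro-degrees by default, rounded from the guarded
    accumulator) and the gain-inflated magnitude K_n·sqrt(x²+y²).
    """
    if x == 0 and y == 0:
        raise ValueError("angle of the zero vector is undefined")
    if x <= 0:
        raise ValueError("inputs must be pre-rotated so that x > 0")
    lut = lut or build_atan_lut(n_iter)
    z, mag = _vectoring_arrays(np.array([x]), np.array([y]), lut)
    angle = (int(z[0]) + _GUARD // 2) >> (_GUARD // 2)  # drop guard bit, round
    return angle, int(mag[0])


def gain_compensate(magnitude_scaled, n_iter: int = 16):
    """Remove the CORDIC gain: magnitude_scaled / K_n to within 1 count.

    Implemented as integer multiplication by a precomputed Q16 reciprocal
    followed by a rounding shift — the shift-add form a fixed-point core
    would use; no division or floating point.
    """
    r = _reciprocal_q16(n_iter)
    m = np.asarray(magnitude_scaled)
    if np.any(m < 0):
        raise ValueError("magnitude must be non-negative")
    out = (m.astype(np.int64) * r + (1 << (_RECIP_BITS - 1))) >> _RECIP_BITS
    return int(out) if np.isscalar(magnitude_scaled) else out


class TiltAngles(NamedTuple):
    """Tilt of one sample, degrees: pitch (body X toward gravity), roll
    (about X), inclination (sensor Z axis vs gravity, 0° = upright)."""

    pitch: float
    roll: float
    inclination: float


def _tilt_arrays(ax: np.ndarray, ay: np.ndarray, az: np.ndarray,
                 lut: AngleLUT, n_iter: int):
    """Vectorised integer tilt pipeline over sample arrays."""
    ax = ax.astype(np.int64)
    ay = ay.astype(np.int64)
    az = az.astype(np.int64)
    n = ax.shape[0]
    if np.any((ax == 0) & (ay == 0) & (az == 0)):
        raise ValueError("zero-magnitude sample: tilt undefined")
    scale = lut.scale

    def vect(x, y):
        """Guarded vectoring on arrays; entries with x <= 0 must be masked
        out by the caller (replaced with 1 to keep the loop total)."""
        safe_x = np.where(x > 0, x, np.int64(1))
        z, mag = _vectoring_arrays(safe_x, y, lut)
        ang = (z + _GUARD // 2) >> (_GUARD // 2)
        return ang, mag

    half_turn = 180 * scale
    quarter_turn = 90 * scale

    # --- roll = atan2(ay, az), quadrant pre-rotation on the sign of az
    roll = np.zeros(n, dtype=np.int64)
    m_yz = np.zeros(n, dtype=np.int64)
    nz = ~((ay == 0) & (az == 0))
    absz = np.abs(az)
    # one vectoring of (|az|, ay) serves both half-planes; fold the angle back
    ang, mag = vect(absz, ay)
    pos = nz & (az > 0)
    roll[pos] = ang[pos]
    neg = nz & (az < 0)
    roll[neg & (ay >= 0)] = half_turn - ang[neg & (ay >= 0)]
    roll[neg & (ay < 0)] = -half_turn - ang[neg & (ay < 0)]
    m_yz[pos | neg] = mag[pos | neg]
    # az == 0: roll = ±90 by the sign of ay; magnitude is K·|ay|
    zed = nz & (az == 0)
    roll[zed] = np.where(ay[zed] > 0, quarter_turn, -quarter_turn)
    ang3, mag3 = vect(np.maximum(np.abs(ay), 1), np.zeros_like(ay))
    m_yz[zed] = mag3[zed]
    # gravity entirely on X: roll defined as 0, m_yz = 0
    m_yz[~nz] = 0

    # --- pitch = atan2(ax, sqrt(ay²+az²)) with the gain-corrected magnitude
    myz_c = np.asarray(gain_compensate(m_yz, n_iter))
    pitch = np.zeros(n, dtype=np.int64)
    has_plane = myz_c > 0
    angp, _ = vect(np.where(has_plane, myz_c, 1), ax)
    pitch[has_plane] = angp[has_plane]
    pitch[~has_plane] = np.where(ax[~has_plane] > 0, quarter_turn, -quarter_turn)

    # --- inclination = atan2(sqrt(ax²+ay²), az) ∈ [0°, 180°]
    absx = np.abs(ax)
    absy = np.abs(ay)
    xy_nz = ~((ax == 0) & (ay == 0))
    big = np.maximum(absx, absy)
    small = np.minimum(absx, absy)
    angm, magm = vect(np.where(xy_nz, big, 1), small)
    m_xy = np.where(xy_nz, np.asarray(gain_compensate(magm, n_iter)), 0)
    incl = np.zeros(n, dtype=np.int64)
    up = az > 0
    down = az < 0
    flat = az == 0
    angi_up, _ = vect(np.where(up, az, 1), m_xy)
    incl[up] = angi_up[up]
    angi_dn, _ = vect(np.where(down, -az, 1), m_xy)
    incl[down] = half_turn - angi_dn[down]
    incl[flat] = quarter_turn
    # a pure -Z sample has m_xy = 0 and az < 0 -> 180° exactly
    incl[~xy_nz & down] = half_turn
    incl[~xy_nz & up] = 0

    to_deg = 1.0 / scale
    return pitch * to_deg, roll * to_deg, incl * to_deg


def tilt_from_counts(sample, n_iter: int = 16,
                     lut: AngleLUT | None = None) -> TiltAngles:
    """Tilt angles of one 3-axis count sample via the integer CORDIC path.

    ``sample`` is an AccelTriplet or any (ax, ay, az[, t]) sequence of
    integer counts.  Raises ValueError on a zero-magnitude sample.
    """
    lut = lut or build_atan_lut(n_iter)
    ax, ay, az = int(sample[0]), int(sample[1]), int(sample[2])
    p, r, i = _tilt_arrays(np.array([ax]), np.array([ay]), np.array([az]), lut, n_iter)
    return TiltAngles(float(p[0]), float(r[0]), float(i[0]))


@dataclass
class TiltStream:
    """Per-sample tilt angles for one channel: arrays aligned with ``t``."""

    t: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    inclination: np.ndarray

    def __len__(self) -> int:
        return self.t.shape[0]


def tilt_stream(t: np.ndarray, counts: np.ndarray, n_iter: int = 16,
                lut: AngleLUT | None = None) -> TiltStream:
    """Run the CORDIC tilt pipeline over an (n, 3) count array."""
    lut = lut or build_atan_lut(n_iter)
    counts = np.asarray(counts)
    p, r, i = _tilt_arrays(counts[:, 0], counts[:, 1], counts[:, 2], lut, n_iter)
    return TiltStream(np.asarray(t, dtype=float), p, r, i)
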