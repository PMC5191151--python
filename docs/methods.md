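# Methods

## Sensor model

Each channel digitises acceleration at ±2 g full scale, 12-bit two's
complement, 100 Hz, with 1 count = 2⁻¹⁰ g ("1 mg"). Quantisation is
round-to-nearest with saturation at [−2048, 2047]; positive full scale is
therefore 2047 counts ≈ 1.999 g. The noise model is i.i.d. Gaussian per
axis (default sd 0.005 g — the quiet end of consumer MEMS accelerometers at
100 Hz bandwidth) plus an optional constant per-axis bias; no spectral
colouring, temperature drift or cross-axis coupling is modelled.

The body frame has Z up the spine, X anterior, Y left; gravity reads
(0, 0, +1 g) on an upright wearer. Orientations are (pitch, roll):
pitch rotates body X toward gravity, so a sensor at (p, r) reads
(sin p, sin r cos p, cos r cos p) g, with inclination
arccos(cos p · cos r). Mounting rotations per placement are exposed as
parameters and default to identity; the garment's true mounting is a free
parameter of the hardware, not of the method.

## Synthetic recordings

The generator covers the study conditions the analytics are specified
under; its defaults are fixed and are what the tests exercise.

- **Static postures**: the rotated gravity vector plus noise, quantised.
- **Walking**: alternating left/right footfalls at the requested cadence.
  Each footfall adds a raised-cosine vertical impulse (default 0.5 g peak,
  0.25 s wide) on the ipsilateral waist channel and a 0.25× echo on the
  contralateral one; the chest pitch is the forward lean plus a ±2°
  oscillation at step frequency; footfall times get 10 ms Gaussian jitter.
  Asymmetry a ∈ [0, 0.5) skews the alternating intervals to
  T_c(2±a)/4 so the injected interval-based symmetry index is exactly
  100·a percent.
- **Events**: scripted kinematic profiles with exact window labels — fall
  (0.3 s at 0.05 g, an 80 ms 4 g impact that saturates the range, then
  lying at 85°), lying-to-sitting (inclination ramp 85°→10° over the ramp
  time), trunk bend and head down (linear ramp, hold, return; the cervical
  channel follows the trunk at 40 % during a trunk bend and the chest stays
  upright during head-down), and body turning while lying (roll sweep at
  constant high inclination).

What the generator does *not* emulate — soft-tissue artefact, sensor
migration on the garment, stair/ramp gait, pathological gait waveforms,
coloured noise — bounds what the passing tests show: they validate the
algorithmic chain under clean, well-posed kinematics, not clinical
performance on real patients.

## Fixed-point CORDIC

The vectoring core keeps all state in integers; the test suite verifies by
interval analysis that every intermediate fits 32 bits for 12-bit inputs at
up to 20 iterations. Numerical choices:

- **Angle unit**: signed micro-degrees (10⁻⁶ °), directly readable against
  degree-denominated specifications; the accumulator carries one extra
  guard bit (half-micro-degree steps, LUT rounded at the doubled scale)
  that is dropped with rounding at the boundary.
- **Input normalisation**: both components are left-shifted by a common
  per-vector amount until max(|x|,|y|) ∈ [2²⁰, 2²¹). The shift is
  angle-invariant and keeps shift-truncation noise below the terminal
  micro-rotation even for few-count vectors; without it, errors on small
  vectors reach ~0.03°, with it the empirical maximum over random 12-bit
  vectors is ~0.002° at 16 iterations.
- **Iterations**: default 16; the residual rotation 2⁻¹⁵ rad ≈ 0.0018°
  dominates the error budget, quantisation of a 1 g vector adds ≤ 0.056°,
  and gain-compensation rounding ≤ 1 count — comfortably inside the 0.5°
  end-to-end accuracy bound with margin.
- **Tie-break**: d = −sign(y) with sign(0) = +1, making the loop total and
  deterministic.
- **Quadrants**: inputs are pre-rotated into x > 0 by sign swaps and the
  octant folded back afterwards, covering pitch ∈ [−90°, 90°],
  roll ∈ (−180°, 180°], inclination ∈ [0°, 180°]. Degenerate samples
  (gravity exactly on one axis) are resolved by convention: roll = 0 when
  Ay = Az = 0; the all-zero sample is an error.
- **Gain removal**: multiplication by round(2¹⁶/K_n) and a rounding right
  shift; exact to within one count over the representable range.

## Posture and event rules

All thresholds live in `AlertRuleConfig`. The hardware's own defaults are
not published, so these are the package's documented choices, each
configurable: lying above 60° chest inclination; head-down above 30°
cervical tilt held 60 s; trunk-bend above 30° chest pitch held 10 s, with
5° hysteresis on release; lying-to-sitting fires when the (0.2 s smoothed)
inclination leaves the lying band and crosses 45° within 10 s, after being
lying for ≥ 2 s; a fall requires < 0.5 g for ≥ 0.2 s, then an impact
(saturated sample or > 1.8 g) within 1 s, then ≥ 5 s of lying — all three
stages, so static lying or walking never fires. Both duration warnings are
gated off while the wearer is lying, since a lying trunk or neck is tilted
by posture rather than by bending. Classification uses 1 s windows with
0.5 s steps; a window whose inclination sweeps > 15° is a transition.
Sitting vs standing cannot be separated by trunk orientation alone; the
package uses the COM-channel pitch (> 15° → sitting) and flags this as a
heuristic.

## Gait

Step detection: zero-phase second-order Butterworth band-pass 0.5–3 Hz on
the vertical waist axis, peaks at least 0.25 s apart above
median + 3·MAD within a rolling 5 s window, with a 0.05 g absolute floor
(the floor is what keeps pure sensor noise from producing steps on static
recordings). Walking intervals are runs of ≥ 4 alternating steps with
gaps < 2 s, padded by half the mean gap.

The step-symmetry index is interval-based: the "left interval" is the time
from a right footfall to the next left footfall and vice versa (plain
left-to-left intervals would equal the stride time on both sides and carry
no asymmetry information). SI = |ĪL − ĪR|/(½(ĪL + ĪR))·100 %; it is
scale-invariant and symmetric under side swap, and requires ≥ 3 steps per
side (`InsufficientStepsError` otherwise). `sd_symmetry` is the sample sd
of the per-cycle instantaneous SI. Trend aggregation uses calendar periods
(monthly by default) with sample sd (n−1); empty periods are present with
n = 0.

## Problem sizes

The validation suite uses 60 s walks (10 seeds per asymmetry level on the
grid {0, 0.05, 0.1, 0.2}), 20 seeds per event kind, 20 static recordings of
10 s for the steady-state checks, a 37×37 orientation grid for the tilt
sweep and 10⁴ random vectors for the CORDIC/atan2 comparison — desk-scale
runs sized to give stable statistics in seconds.

## Known limitations

- Postures are derived from static gravity only; sustained non-gravitational
  acceleration (vehicles, elevators) will be misread as tilt.
- The fall signature is a stylised three-stage template; real falls vary.
- Sitting/standing disambiguation is heuristic (see above).
- The frame protocol models loss only as sequence gaps, not corruption.
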