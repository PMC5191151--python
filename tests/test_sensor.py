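"""Sensor model: quantisation, orientation and the synthetic generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posturekit import (
    Placement,
    Recording,
    SensorSpec,
    dequantize,
    gravity_in_sensor,
    quantize,
    quantize_sample,
    simulate_event,
    simulate_static,
    simulate_walk,
)


class TestQuantize:
    @pytest.mark.parametrize("accel_g, expected", [
        ((0.0, 0.0, 1.0), (0, 0, 1024)),        # 1 g on the vertical axis
        ((0.0, 0.0, 9.9), (0, 0, 2047)),        # saturation at +full scale
        ((0.0, 0.0, -9.9), (0, 0, -2048)),      # saturation at -full scale
        ((2.0 ** -10, 0.0, 0.0), (1, 0, 0)),    # the 1 mg sensitivity step
    ])
    def test_examples(self, accel_g, expected):
        s = quantize_sample(accel_g)
        assert (s.ax, s.ay, s.az) == expected

    def test_defaults_reproduce_sensor_triple(self, default_spec):
        # ±2 g, 12-bit, 1 count = 2^-10 g: lsb * 2^(bits-2) spans half scale
        assert default_spec.lsb_g * 2 ** (default_spec.resolution_bits - 2) == \
            pytest.approx(default_spec.range_g / 2)
        assert default_spec.lsb_g == pytest.approx(1.0 / 1024)
        assert default_spec.sample_rate_hz == 100.0

    def test_one_lsb_step_changes_output_by_one_count(self, default_spec):
        lsb = default_spec.lsb_g
        base = np.arange(-1000, 1001) * lsb
        c0 = quantize(base, default_spec)
        c1 = quantize(base + lsb, default_spec)
        assert np.all(c1 - c0 == 1)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            quantize_sample((np.nan, 0.0, 0.0))

    @given(a=st.floats(-3, 3, allow_nan=False), b=st.floats(-3, 3, allow_nan=False))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_monotone_and_odd_symmetric(self, a, b):
        lo, hi = sorted((a, b))
        cl, ch = quantize([lo], None)[0], quantize([hi], None)[0]
        assert cl <= ch
        # odd symmetry away from the asymmetric saturation corner
        if abs(a) < 1.9:
            assert quantize([-a], None)[0] == -quantize([a], None)[0]

    def test_validation(self):
        with pytest.raises(ValueError):
            SensorSpec(resolution_bits=7)
        with pytest.raises(ValueError):
            SensorSpec(sample_rate_hz=0)


class TestStatic:
    def test_upright_noiseless_is_pure_vertical(self, quiet_spec):
        rec = simulate_static(0.0, 0.0, 2.0, quiet_spec, seed=0)
        for p in Placement:
            assert (rec.channels[p] == [0, 0, 1024]).all()

    def test_pitch_90_puts_gravity_on_x(self, quiet_spec):
        rec = simulate_static(90.0, 0.0, 1.0, quiet_spec, seed=0)
        assert (rec.channels[Placement.CHEST] == [1024, 0, 0]).all()

    def test_roundtrip_recovers_gravity_within_half_lsb(self, quiet_spec):
        g = gravity_in_sensor(37.0, -12.0)
        rec = simulate_static(37.0, -12.0, 1.0, quiet_spec, seed=0)
        back = dequantize(rec.channels[Placement.CHEST][0], quiet_spec)
        assert np.all(np.abs(back - g) <= quiet_spec.lsb_g / 2 + 1e-12)

    @pytest.mark.parametrize("pitch,roll", [(0, 0), (30, 0), (-45, 60), (80, -80)])
    def test_noiseless_magnitude_is_one_g(self, quiet_spec, pitch, roll):
        rec = simulate_static(pitch, roll, 1.0, quiet_spec, seed=0)
        mag = rec.magnitude_g(Placement.COM_L3)
        # three axes each off by at most half an LSB
        assert np.all(np.abs(mag - 1.0) < 3 * quiet_spec.lsb_g)

    def test_steady_state_mean_and_sd_within_3pct(self):
        spec = SensorSpec(noise_sd_g=0.01)
        rec = simulate_static(30.0, 0.0, 10.0, spec, seed=1)
        mag = rec.magnitude_g(Placement.CHEST)
        assert abs(mag.mean() - 1.0) < 0.03
        assert mag.std(ddof=1) < 0.03

    def test_determinism(self, default_spec):
        a = simulate_static(10, 5, 2, default_spec, seed=42)
        b = simulate_static(10, 5, 2, default_spec, seed=42)
        for p in Placement:
            assert (a.channels[p] == b.channels[p]).all()

    def test_duration_too_short_rejected(self, default_spec):
        with pytest.raises(ValueError):
            simulate_static(0, 0, 0.5, default_spec, seed=0)


class TestWalk:
    def test_label_count_matches_cadence(self, default_spec):
        rec = simulate_walk(100, 60, spec=default_spec, seed=1)
        n = len(rec.labels_of("step_left")) + len(rec.labels_of("step_right"))
        # cadence 100 over ~59 s of stepping span
        assert abs(n - 100) <= 2

    def test_zero_asymmetry_gives_equal_intervals(self, default_spec):
        rec = simulate_walk(110, 60, asymmetry=0.0, spec=default_spec,
                            seed=2, step_jitter_s=0.0)
        lt = np.array([l.start for l in rec.labels_of("step_left")])
        rt = np.array([l.start for l in rec.labels_of("step_right")])
        assert np.diff(lt).std() < 1e-9
        assert abs(np.diff(lt).mean() - np.diff(rt).mean()) < 1e-9

    def test_lean_recovered_by_float_arctangent_oracle(self, quiet_spec):
        rec = simulate_walk(100, 30, lean_deg=10.0, spec=quiet_spec, seed=3)
        c = dequantize(rec.channels[Placement.CHEST], quiet_spec)
        pitch = np.degrees(np.arctan2(c[:, 0], np.hypot(c[:, 1], c[:, 2])))
        assert abs(pitch.mean() - 10.0) < 0.2

    def test_parameter_validation(self, default_spec):
        with pytest.raises(ValueError):
            simulate_walk(30, 60, spec=default_spec, seed=0)
        with pytest.raises(ValueError):
            simulate_walk(100, 60, asymmetry=0.6, spec=default_spec, seed=0)
        with pytest.raises(ValueError):
            simulate_walk(100, 1.5, spec=default_spec, seed=0)


class TestEvents:
    def test_lying_to_sitting_crosses_45_once_inside_window(self, quiet_spec):
        rec = simulate_event("lying_to_sitting", quiet_spec, seed=0, ramp_s=2.0)
        c = dequantize(rec.channels[Placement.CHEST], quiet_spec)
        incl = np.degrees(np.arccos(np.clip(
            c[:, 2] / np.linalg.norm(c, axis=1), -1, 1)))
        below = incl < 45.0
        crossings = np.flatnonzero(np.diff(below.astype(int)) == 1)
        assert crossings.size == 1
        (lab,) = rec.labels_of("lying_to_sitting")
        assert lab.start <= rec.t[crossings[0]] <= lab.end

    def test_fall_contains_saturated_impact(self, default_spec):
        rec = simulate_event("fall", default_spec, seed=1)
        c = rec.channels[Placement.COM_L3]
        assert np.any((c >= default_spec.count_max) | (c <= default_spec.count_min))

    def test_trunk_bend_label_length_is_hold(self, default_spec):
        rec = simulate_event("trunk_bend", default_spec, seed=2,
                             angle_deg=40.0, hold_s=30.0)
        (lab,) = rec.labels_of("trunk_bend")
        assert lab.end - lab.start == pytest.approx(30.0)

    def test_unknown_kind_rejected(self, default_spec):
        with pytest.raises(ValueError, match="unknown event kind"):
            simulate_event("teleport", default_spec, seed=0)


class TestRecording:
    def test_shared_timestamps_enforced(self, default_spec):
        t = np.arange(10) / default_spec.sample_rate_hz
        chans = {Placement.CHEST: np.zeros((9, 3), dtype=int)}
        with pytest.raises(ValueError):
            Recording(default_spec, t, chans)

    def test_non_uniform_timestamps_rejected(self, default_spec):
        t = np.array([0.0, 0.01, 0.5])
        chans = {Placement.CHEST: np.ones((3, 3), dtype=int)}
        with pytest.raises(ValueError):
            Recording(default_spec, t, chans)
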