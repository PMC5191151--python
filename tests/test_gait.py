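"""Step detection, symmetry index and trend aggregation."""

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posturekit import (
    GaitSummary,
    InsufficientStepsError,
    Placement,
    Recording,
    SensorSpec,
    StepSeries,
    aggregate_trend,
    detect_steps,
    simulate_static,
    simulate_walk,
    step_symmetry_index,
    walk_summary,
)


def _series(left, right):
    return StepSeries(np.asarray(left, float), np.asarray(right, float))


class TestDetectSteps:
    def test_recovers_labeled_step_count(self):
        rec = simulate_walk(100, 60, seed=1)
        truth = len(rec.labels_of("step_left")) + len(rec.labels_of("step_right"))
        assert abs(detect_steps(rec).n_steps - truth) <= 2

    def test_static_recording_has_no_steps(self):
        rec = simulate_static(0.0, 0.0, 10.0, seed=2)
        assert detect_steps(rec).n_steps == 0

    def test_seed_stability_of_step_count(self):
        counts = [detect_steps(simulate_walk(100, 30, seed=s)).n_steps
                  for s in range(10)]
        assert max(counts) - min(counts) <= 2

    def test_missing_channel_named_in_error(self):
        rec = simulate_walk(100, 30, seed=3)
        del rec.channels[Placement.WAIST_LEFT]
        with pytest.raises(KeyError, match="WAIST_LEFT"):
            detect_steps(rec)


class TestSymmetryIndex:
    def test_identical_intervals_are_symmetric(self):
        left = np.arange(0.5, 10, 1.0)
        right = left + 0.5
        assert step_symmetry_index(_series(left, right)) == pytest.approx(0.0)

    def test_known_asymmetry_closed_form(self):
        # left interval 0.55 s, right 0.45 s -> |0.10| / 0.50 = 20 %
        starts = np.arange(10) * 1.0
        left = starts + 0.55            # right at k, left 0.55 later
        right = starts[1:]              # next right 0.45 after the left
        si = step_symmetry_index(_series(left, right))
        assert si == pytest.approx(20.0, abs=1e-9)

    def test_insufficient_steps_signaled(self):
        with pytest.raises(InsufficientStepsError):
            step_symmetry_index(_series([1.0, 2.0], [1.5, 2.5]))

    @given(scale=st.floats(0.2, 5.0), shift=st.floats(0, 10))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_scale_and_shift_invariance(self, scale, shift):
        starts = np.arange(8) * 1.0
        left = starts + 0.6
        right = starts[1:]
        base = step_symmetry_index(_series(left, right))
        scaled = step_symmetry_index(_series(left * scale + shift,
                                             right * scale + shift))
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_side_swap_invariance(self):
        starts = np.arange(8) * 1.1
        left = starts + 0.62
        right = starts[1:]
        a = step_symmetry_index(_series(left, right))
        b = step_symmetry_index(_series(right, left))
        assert a == pytest.approx(b)

    def test_recovers_injected_asymmetry(self):
        for a in (0.0, 0.1, 0.2):
            si = step_symmetry_index(detect_steps(simulate_walk(
                100, 60, asymmetry=a, seed=5)))
            assert abs(si - 100 * a) <= 2.0


class TestWalkSummary:
    def test_lean_angle_recovered(self):
        s = walk_summary(simulate_walk(100, 60, lean_deg=10.0, seed=6))
        assert s.mean_forward_lean == pytest.approx(10.0, abs=1.0)

    def test_walk_then_rest_walk_time(self):
        spec = SensorSpec()
        w = simulate_walk(100, 60, seed=7)
        st_rec = simulate_static(0.0, 0.0, 60.0, spec, seed=7)
        t = np.arange(w.t.size + st_rec.t.size) / spec.sample_rate_hz
        chans = {p: np.vstack([w.channels[p], st_rec.channels[p]])
                 for p in Placement}
        rec = Recording(spec, t, chans, w.labels, 7)
        s = walk_summary(rec)
        assert abs(s.walk_time - 60.0) <= 2.0

    def test_static_recording_degenerates_gracefully(self):
        s = walk_summary(simulate_static(0.0, 0.0, 10.0, seed=8))
        assert s.n_steps == 0
        assert s.symmetry_index is None
        assert s.mean_forward_lean is None

    def test_summary_internally_consistent(self):
        rec = simulate_walk(100, 45, asymmetry=0.1, seed=9)
        s = walk_summary(rec)
        assert s.walk_time <= rec.duration
        assert s.symmetry_index >= 0
        assert s.n_steps >= 0


class TestTrend:
    @staticmethod
    def _summary(si, lean, d):
        return GaitSummary(100, 60.0, si, lean, 1.0, d)

    def test_constant_summaries_give_flat_trend(self):
        summaries = [self._summary(12.0, 8.0, date(2024, m, 15))
                     for m in range(1, 13)]
        tab = aggregate_trend(summaries).table
        assert len(tab) == 12
        assert np.allclose(tab["mean_symmetry"], 12.0)
        assert np.allclose(tab["mean_lean"], 8.0)

    def test_drifting_lean_gives_increasing_means(self):
        leans = np.linspace(5, 15, 12)
        summaries = [self._summary(10.0, l, date(2024, m, 10))
                     for m, l in zip(range(1, 13), leans)]
        tab = aggregate_trend(summaries).table
        assert (np.diff(tab["mean_lean"]) > 0).all()

    def test_two_summaries_in_one_month(self):
        summaries = [self._summary(10.0, 5.0, date(2024, 3, 5)),
                     self._summary(20.0, 7.0, date(2024, 3, 20))]
        tab = aggregate_trend(summaries).table
        assert tab.loc[0, "mean_symmetry"] == pytest.approx(15.0)
        assert tab.loc[0, "sd_symmetry"] == pytest.approx(np.std([10, 20], ddof=1))

    def test_empty_months_present_but_marked(self):
        summaries = [self._summary(10.0, 5.0, date(2024, 1, 5)),
                     self._summary(12.0, 6.0, date(2024, 4, 5))]
        tab = aggregate_trend(summaries).table
        assert len(tab) == 4
        assert tab["n"].tolist() == [1, 0, 0, 1]

    def test_undated_summaries_rejected(self):
        with pytest.raises(ValueError):
            aggregate_trend([self._summary(10.0, 5.0, None)])
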