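"""Magnitudes, envelope conditioning, stride/stance/swing/step detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from imugait import (
    FilterConfig,
    StrideEvent,
    StrideSet,
    condition_signal,
    detect_steps,
    detect_strides,
    magnitude,
    split_stance_swing,
)
from imugait.errors import InputError, ParameterError
from imugait.pipeline import process_leg


class TestMagnitude:
    def test_pythagorean_triple(self):
        assert magnitude(np.array([[3.0, 4.0, 0.0]]))[0] == pytest.approx(5.0)

    def test_zero_series(self):
        np.testing.assert_array_equal(magnitude(np.zeros((5, 3))), np.zeros(5))

    def test_rotation_invariance(self, rng):
        v = rng.normal(size=(50, 3))
        rot = Rotation.from_rotvec([0.3, 1.0, -0.4])
        np.testing.assert_allclose(magnitude(rot.apply(v)), magnitude(v), atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            magnitude(np.array([[np.inf, 0, 0]]))


class TestConditionSignal:
    def test_constant_input_maps_to_zero(self):
        out = condition_signal(np.full(300, 3.7))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_output_mean_is_zero(self, rng):
        out = condition_signal(rng.normal(size=(400, 3)))
        assert abs(out.mean()) < 1e-9

    def test_pulse_train_yields_one_lobe_per_pulse(self):
        """n acceleration bursts → n dominant envelope lobes."""
        fs, n_pulses = 50.0, 6
        t = np.arange(int(12 * fs)) / fs
        x = np.zeros((t.size, 3))
        for k in range(n_pulses):
            m = (t >= 2 * k + 0.6) & (t < 2 * k + 1.4)
            x[m, 0] = 5.0 * np.sin(np.pi * (t[m] - 2 * k - 0.6) / 0.8)
        cen = condition_signal(x, FilterConfig(hp_cut=0.3, fs=fs))
        # lobes = contiguous regions above half the envelope max
        above = cen > 0.5 * cen.max()
        n_lobes = int(np.sum(np.diff(above.astype(int)) == 1))
        assert n_lobes == n_pulses

    def test_too_short_series_rejected(self):
        with pytest.raises(InputError):
            condition_signal(np.ones(10))

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            FilterConfig(hp_cut=6.0, lp_cut=5.0)


class TestDetectStrides:
    def test_cosine_troughs_found(self):
        fs, periods = 50.0, 10
        t = np.arange(int(periods * fs)) / fs  # 1 Hz cosine
        cen = np.cos(2 * np.pi * t)
        ss = detect_strides(cen, t, fs=fs, merge_short_fraction=0.0)
        # troughs at t = 0.5, 1.5, ... 9.5
        assert len(ss.minima_t) == periods
        np.testing.assert_allclose(ss.minima_t, np.arange(periods) + 0.5, atol=0.03)

    def test_constant_signal_has_no_strides(self):
        t = np.arange(100) / 50.0
        ss = detect_strides(np.zeros(100), t)
        assert len(ss.minima_idx) == 0

    def test_flat_minimum_resolves_to_lowest_index(self):
        t = np.arange(400) / 50.0
        cen = np.cos(2 * np.pi * 0.5 * t)
        flat = (t >= 0.9) & (t <= 1.1)  # flatten the first trough
        cen[flat] = cen[np.argmin(np.abs(t - 0.9))]
        ss = detect_strides(cen, t, fs=50.0)
        first = ss.minima_t[0]
        assert first == pytest.approx(0.9, abs=0.021)

    def test_offset_and_gain_invariance(self, slow_pair):
        """Centering + SD-relative prominence ⇒ same minima under a·x + b."""
        left, _, _ = slow_pair
        leg = process_leg(left)
        t = leg.recording.t
        base = detect_strides(leg.centered, t)
        scaled = detect_strides(3.7 * leg.centered + 1.9, t)
        np.testing.assert_array_equal(base.minima_idx, scaled.minima_idx)

    def test_short_fragment_merged(self):
        fs = 50.0
        t = np.arange(int(10 * fs)) / fs
        cen = np.cos(2 * np.pi * 0.5 * t)  # minima every 2 s
        # inject a narrow spurious dip mid-cycle
        dip = np.exp(-(((t - 4.5) / 0.05) ** 2)) * 2.5
        ss = detect_strides(cen - dip, t, fs=fs)
        gaps = np.diff(ss.minima_t)
        assert np.all(gaps > 1.0)


class TestSplitStanceSwing:
    def _strideset(self, t, idx):
        return StrideSet(
            minima_idx=np.asarray(idx),
            minima_t=t[np.asarray(idx)],
            minima_values=np.zeros(len(idx)),
        )

    def test_triangular_pulse_apex_is_ss(self):
        t = np.arange(100) / 50.0
        at = np.zeros(100)
        at[20:41] = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        ss = split_stance_swing(at, self._strideset(t, [5, 80]), t)
        assert ss.strides[0].mid_idx == 30
        assert ss.strides[0].stance_time > 0 and ss.strides[0].swing_time > 0

    def test_tied_maxima_take_lower_index(self):
        t = np.arange(100) / 50.0
        at = np.zeros(100)
        at[30] = at[60] = 1.0
        ss = split_stance_swing(at, self._strideset(t, [5, 90]), t)
        assert ss.strides[0].mid_idx == 30

    def test_monotone_window_is_degenerate(self):
        t = np.arange(50) / 50.0
        at = np.linspace(0, 1, 50)
        ss = split_stance_swing(at, self._strideset(t, [0, 49]), t)
        assert ss.n_strides == 0
        assert ss.n_degenerate == 1

    def test_overlong_window_treated_as_turn(self):
        t = np.arange(500) / 50.0
        at = np.abs(np.sin(2 * np.pi * 0.4 * t))
        ss = split_stance_swing(at, self._strideset(t, [0, 450]), t, max_stride_s=6.0)
        assert ss.n_strides == 0
        assert ss.n_long_excluded == 1

    def test_stance_swing_partition_is_exact(self, slow_pair):
        left, _, _ = slow_pair
        leg = process_leg(left)
        for s in leg.strides.strides:
            assert s.start_idx < s.mid_idx < s.end_idx
            assert s.stance_time + s.swing_time == pytest.approx(s.stride_time)

    def test_recovered_stance_fraction(self, slow_pair):
        """60:40 stance:swing split recovered within ±0.1 per stride."""
        left, _, truth = slow_pair
        leg = process_leg(left)
        fracs = [
            (s.mid_t - s.start_t) / (s.end_t - s.start_t)
            for s in leg.strides.strides
        ]
        assert abs(np.mean(fracs) - 0.6) < 0.1


def _strides_from_times(times, side):
    strides = [
        StrideEvent(
            int(a * 50), int((a + b) / 2 * 50), int(b * 50), float(a), (a + b) / 2, float(b)
        )
        for a, b in zip(times[:-1], times[1:])
    ]
    return StrideSet(
        minima_idx=np.array([s.start_idx for s in strides] + [strides[-1].end_idx]),
        minima_t=np.asarray(times, float),
        minima_values=np.zeros(len(times)),
        strides=strides,
        side=side,
    )


class TestDetectSteps:
    def test_interleaved_contacts_pair_up(self):
        left = _strides_from_times([0.0, 2.0, 4.0], "left")
        right = _strides_from_times([1.0, 3.0, 5.0], "right")
        steps = detect_steps(left, right)
        spans = [(s.start_t, s.end_t) for s in steps]
        assert spans == [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0)]
        assert [s.side for s in steps] == ["right", "left", "right", "left"]

    def test_single_foot_yields_no_steps(self):
        left = _strides_from_times([0.0, 2.0], "left")
        empty = StrideSet(np.empty(0, int), np.empty(0), np.empty(0), side="right")
        assert detect_steps(left, empty) == []

    def test_one_step_per_stride_per_leg(self, slow_pair):
        l, r, truth = slow_pair
        from imugait.pipeline import run_pipeline

        rep = run_pipeline(l, r)
        for side in ("left", "right"):
            own = [s for s in rep.steps if s.side == side and not s.anomalous]
            assert len(own) == rep.legs[side].strides.n_strides

    def test_alternation_when_contacts_alternate(self):
        left = _strides_from_times([0.0, 2.0, 4.0, 6.0], "left")
        right = _strides_from_times([1.0, 3.0, 5.0, 7.0], "right")
        sides = [s.side for s in detect_steps(left, right)]
        assert all(a != b for a, b in zip(sides[:-1], sides[1:]))

    def test_missed_contralateral_closes_anomalous(self):
        left = _strides_from_times([0.0, 2.0, 4.0], "left")
        right = _strides_from_times([9.0, 11.0], "right")
        steps = detect_steps(left, right)
        assert any(s.anomalous for s in steps)
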