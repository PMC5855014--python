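"""Feature table, asymmetry, accuracy statistic and validation summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imugait import accuracy, asymmetry, symmetry_index, validation_stats
from imugait.datasets import OLDER_ADULT_TRIAL, load_validation_table
from imugait.errors import InputError, ParameterError
from imugait.pipeline import run_pipeline


class TestAccuracy:
    @pytest.mark.parametrize(
        "actual,estimated,expected",
        [
            (21.03, 20.59, 97.91),  # worked single-subject trial, right leg
            (21.03, 20.47, 97.34),  # left leg
            (7.650, 7.607, 99.438),
            (7.693, 6.784, 88.184),
        ],
    )
    def test_worked_examples(self, actual, estimated, expected):
        # published values carry the print rounding of their inputs
        assert accuracy(actual, estimated) == pytest.approx(expected, abs=0.005)

    def test_identity_is_hundred(self):
        assert accuracy(3.14, 3.14) == 100.0

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ParameterError):
            accuracy(0.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0.1, 100), st.floats(0.0, 150), st.floats(0.01, 50)
    )
    def test_scale_invariance(self, a, e, c):
        assert accuracy(c * a, c * e) == pytest.approx(accuracy(a, e), abs=1e-6)

    def test_bounded_above_by_hundred(self):
        assert accuracy(5.0, 7.0) < 100.0


class TestValidationStats:
    def test_reference_study_distances(self):
        """The bundled 20-leg motion-capture comparison reproduces its
        published summary: mean accuracy 97.57 %, 95 % CI 1.327, r = 0.81,
        column means 7.67 / 7.49."""
        df = load_validation_table()
        out = validation_stats(
            df["reference_distance_m"].to_numpy(),
            df["estimated_distance_m"].to_numpy(),
        )
        assert out["mean_accuracy"] == pytest.approx(97.57, abs=0.02)
        assert out["ci_half_width"] == pytest.approx(1.327, abs=0.002)
        assert out["pearson_r"] == pytest.approx(0.81, abs=0.005)
        assert out["mean_reference"] == pytest.approx(7.67, abs=0.005)
        assert out["mean_estimated"] == pytest.approx(7.49, abs=0.005)
        assert out["sd_reference"] == pytest.approx(0.26, abs=0.005)
        assert out["sd_estimated"] == pytest.approx(0.39, abs=0.005)

    def test_reference_study_periods(self):
        df = load_validation_table()
        out = validation_stats(
            df["reference_period_s"].to_numpy(),
            df["estimated_period_s"].to_numpy(),
        )
        assert out["mean_accuracy"] == pytest.approx(99.01, abs=0.02)

    def test_identical_columns(self):
        x = np.array([1.0, 2.0, 3.0])
        out = validation_stats(x, x.copy())
        assert out["mean_accuracy"] == 100.0
        assert out["ci_half_width"] == 0.0
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_constant_column_has_undefined_r(self):
        out = validation_stats(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        assert out["pearson_r"] is None

    def test_single_pair_rejected(self):
        with pytest.raises(InputError):
            validation_stats(np.array([1.0]), np.array([1.0]))


class TestFeatureTable:
    def test_cadence_matches_reference_trial(self):
        """30 steps in 99.3 s → 18.13 steps/min (and the count inverts)."""
        steps, total = OLDER_ADULT_TRIAL["steps_per_leg"], OLDER_ADULT_TRIAL["total_time_s"]
        cadence = steps / (total / 60.0)
        assert cadence == pytest.approx(18.13, abs=0.005)
        assert cadence * total / 60.0 == pytest.approx(steps)

    def test_stride_velocity_is_ratio_of_means(self):
        assert 0.69 / 2.80 == pytest.approx(0.25, abs=0.005)

    def test_walk_velocity_worked_example(self):
        assert OLDER_ADULT_TRIAL["actual_distance_m"] / OLDER_ADULT_TRIAL[
            "total_time_s"
        ] == pytest.approx(0.21, abs=0.005)

    def test_pipeline_table_consistency(self, slow_pair):
        left, right, truth = slow_pair
        rep = run_pipeline(left, right)
        for side in ("left", "right"):
            tab = rep.features[side]
            # stride time = stance + swing, per construction
            assert tab.value("stride_time_s") == pytest.approx(
                tab.value("stance_time_s") + tab.value("swing_time_s"), abs=1e-9
            )
            # variance = SD², swing length = stride length (ZUPT stance)
            assert tab.value("stride_length_m", "var") == pytest.approx(
                tab.value("stride_length_m", "std") ** 2, abs=1e-9
            )
            assert tab.value("swing_length_m") == pytest.approx(
                tab.value("stride_length_m"), abs=1e-9
            )
            # cadence × time/60 returns the step count
            assert tab.value("cadence_steps_per_min") * tab.total_time / 60 == (
                pytest.approx(tab.n_steps)
            )
            assert tab.value("step_ratio") == pytest.approx(
                tab.value("step_length_m") / tab.value("cadence_steps_per_min")
            )

    def test_single_stride_degenerate_stats(self):
        from imugait.events import StrideEvent, StrideSet
        from imugait.features import compute_features
        from imugait.kinematics import StrideKinematics

        s = StrideEvent(0, 30, 50, 0.0, 0.6, 1.0)
        d = np.zeros((50, 3))
        d[-1, 0] = 0.8
        kin = [
            StrideKinematics(
                stride=s,
                t=np.linspace(0, 1, 50),
                v=np.zeros((50, 3)),
                v_drift_free=np.zeros((50, 3)),
                d=d,
                td=0.8,
            )
        ]
        ss = StrideSet(np.array([0]), np.array([0.0]), np.zeros(1), [s])
        tab = compute_features(ss, [], kin, total_time=1.0)
        assert tab.value("stride_length_m", "std") == 0.0
        assert tab.value("stride_length_m", "min") == tab.value("stride_length_m", "max")


class TestAsymmetry:
    def test_symmetric_gait_has_small_differences(self, slow_pair):
        """Perfectly symmetric synthetic gait: timing differences below the
        sampling resolution scale, length differences < 3 %."""
        left, right, truth = slow_pair
        rep = run_pipeline(left, right)
        asym = rep.asym
        dt = asym.table.loc["stride_time_s", "abs_difference"]
        assert dt < 0.04  # 2 samples at 50 Hz
        dl = asym.table.loc["stride_length_m", "abs_difference"]
        assert dl / asym.table.loc["stride_length_m", "right"] < 0.03

    def test_swapping_sides_negates_differences(self, slow_pair):
        left, right, truth = slow_pair
        rep = run_pipeline(left, right)
        fwd = asymmetry(rep.features["right"], rep.features["left"])
        rev = asymmetry(rep.features["left"], rep.features["right"])
        np.testing.assert_allclose(
            fwd.table["difference"].to_numpy(float),
            -rev.table["difference"].to_numpy(float),
            atol=1e-12,
        )

    def test_identical_tables_are_symmetric(self, slow_pair):
        left, right, truth = slow_pair
        rep = run_pipeline(left, right)
        same = asymmetry(rep.features["right"], rep.features["right"])
        np.testing.assert_allclose(
            same.table["difference"].to_numpy(float), 0.0, atol=1e-12
        )

    def test_imposed_stride_time_ratio_recovered(self):
        """Right/left stride-time ratio of 1.15 recovered within ±0.05."""
        from imugait import SyntheticGaitSpec, generate_pair

        spec = SyntheticGaitSpec(
            n_strides=10, stride_time=(2.8 * 1.15, 2.8), seed=21
        )
        l, r, truth = generate_pair(spec)
        rep = run_pipeline(l, r)
        ratio = rep.features["right"].value("stride_time_s") / rep.features[
            "left"
        ].value("stride_time_s")
        assert ratio == pytest.approx(1.15, abs=0.05)


class TestSymmetryIndices:
    def test_robinson_zero_at_symmetry(self):
        assert symmetry_index("robinson", 1.0, 1.0) == 0.0

    def test_log_ratio_and_angle(self):
        assert symmetry_index("log_ratio", 1.0, 1.0) == 0.0
        assert symmetry_index("symmetry_angle", 1.0, 1.0) == pytest.approx(0.0)
        assert symmetry_index("robinson", 0.9, 1.1) == pytest.approx(20.0)

    def test_unknown_index_rejected(self):
        with pytest.raises(ParameterError):
            symmetry_index("nope", 1.0, 1.0)
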