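"""Input-function construction: ROI extraction, corrections, agreement metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pgpkin as pk
from pgpkin.curves import FrameSchedule, TimeActivityCurve
from pgpkin.input_function import (
    ParentFractionCurve,
    apply_metabolite_correction,
    auc_percent_difference,
    correct_dispersion,
    extract_roi_tac,
    fit_parent_fraction,
    k1k2_error_percent,
    resample_to_fine,
    whole_blood_to_plasma,
)


def _tac(durations, values, **kw):
    return TimeActivityCurve(FrameSchedule.from_durations(durations), values, **kw)


class TestExtractRoiTac:
    def test_uniform_region_gives_constant_tac(self, schedule):
        image = np.full((3, 3, 3, len(schedule)), 5.0)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = mask[0, 0, 0] = True
        tac = extract_roi_tac(image, mask, schedule)
        np.testing.assert_allclose(tac.values, 5.0)
        assert tac.source == "image-ROI"

    def test_single_voxel_mask_returns_that_series(self, schedule):
        rng = np.random.default_rng(0)
        image = rng.uniform(0, 10, size=(2, 2, 2, len(schedule)))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[1, 0, 1] = True
        tac = extract_roi_tac(image, mask, schedule)
        np.testing.assert_array_equal(tac.values, image[1, 0, 1, :])

    def test_mean_of_three_voxels(self, schedule):
        image = np.zeros((3, 1, 1, len(schedule)))
        image[0, 0, 0, :], image[1, 0, 0, :], image[2, 0, 0, :] = 2.0, 4.0, 9.0
        tac = extract_roi_tac(image, np.ones((3, 1, 1), bool), schedule)
        np.testing.assert_allclose(tac.values, 5.0)

    def test_empty_mask_error_names_the_label(self, wt1_truth):
        gt = pk.GroundTruth(kinetics={"brain": wt1_truth})
        phantom, _ = pk.build_phantom(gt)
        phantom.label_names["spleen"] = 9  # label with no voxels
        with pytest.raises(ValueError, match="spleen"):
            extract_roi_tac(phantom, "spleen")

    def test_frame_count_mismatch_rejected(self, schedule):
        image = np.zeros((2, 2, 2, 5))
        with pytest.raises(ValueError, match="frames"):
            extract_roi_tac(image, np.ones((2, 2, 2), bool), schedule)


class TestCorrectDispersion:
    def test_constant_curve_unchanged_for_any_tau(self):
        tac = _tac([5.0] * 10, np.full(10, 3.0))
        for tau in (0.0, 5.0, 28.0):
            np.testing.assert_allclose(correct_dispersion(tac, tau).values, 3.0)

    def test_tau_zero_is_identity(self):
        tac = _tac([5.0] * 6, np.arange(6.0))
        np.testing.assert_array_equal(correct_dispersion(tac, 0.0).values, tac.values)

    def test_recovers_ramp_from_closed_form_pair(self):
        """g(t) = t - 28(1 - e^(-t/28)) corrected with tau=28 gives back t."""
        tau = 28.0
        sched = FrameSchedule.from_durations([1.0] * 600)
        mid = sched.midpoints_s
        g = mid - tau * (1.0 - np.exp(-mid / tau))
        rec = correct_dispersion(TimeActivityCurve(sched, g), tau)
        # interior points: central differences are near-exact on the smooth pair
        assert np.max(np.abs(rec.values[1:-1] - mid[1:-1])) < 0.01

    def test_round_trip_with_forward_blur(self, fine_t):
        smooth = pk.forward_disperse(
            fine_t, pk.bolus_input(pk.default_bolus(), fine_t), 28.0
        )
        g = pk.forward_disperse(fine_t, smooth, 28.0)
        sched = FrameSchedule.from_durations([0.5] * 3600)
        tac = TimeActivityCurve(sched, np.interp(sched.midpoints_s, fine_t, g))
        rec = correct_dispersion(tac, 28.0)
        truth = np.interp(sched.midpoints_s, fine_t, smooth)
        assert np.max(np.abs(rec.values - truth)) / smooth.max() < 0.01

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            correct_dispersion(_tac([5.0, 5.0], [1.0, 2.0]), 28.0)

    def test_coarse_sampling_warns(self):
        tac = _tac([60.0] * 5, np.arange(5.0))
        with pytest.warns(UserWarning, match="tau_disp"):
            correct_dispersion(tac, 28.0)

    def test_optional_smoothing_changes_noisy_output(self):
        rng = np.random.default_rng(1)
        vals = 10.0 + rng.normal(0, 1, 30)
        tac = _tac([5.0] * 30, np.clip(vals, 0, None))
        rough = correct_dispersion(tac, 28.0)
        smooth = correct_dispersion(tac, 28.0, smooth=True)
        assert np.std(np.diff(smooth.values)) < np.std(np.diff(rough.values))


class TestParentFraction:
    def test_model_is_anchored_at_one(self):
        model = fit_parent_fraction(pk.reference.PARENT_FRACTIONS["WT-saline"])
        assert model(0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "group,t,expected",
        [
            ("WT-saline", 1.0, 0.95),
            ("WT-saline", 10.0, 0.72),
            ("WT-saline", 30.0, 0.53),
            ("WT-cyclo", 30.0, 0.23),
            ("KO", 1.0, 0.98),
            ("KO", 10.0, 0.51),
        ],
    )
    def test_model_passes_through_measured_samples(self, group, t, expected):
        model = fit_parent_fraction(pk.reference.PARENT_FRACTIONS[group])
        assert model(t) == pytest.approx(expected)

    def test_interpolation_is_linear_between_samples(self):
        model = fit_parent_fraction(pk.reference.PARENT_FRACTIONS["WT-saline"])
        w = (5.5 - 1.0) / (10.0 - 1.0)
        assert model(5.5) == pytest.approx((1 - w) * 0.95 + w * 0.72)

    def test_flat_extrapolation_beyond_last_sample(self):
        model = fit_parent_fraction(pk.reference.PARENT_FRACTIONS["WT-saline"])
        assert model(45.0) == pytest.approx(0.53)

    def test_output_clamped_to_unit_interval(self):
        model = fit_parent_fraction([(1.0, 1.0), (10.0, 0.0)])
        assert np.all(model(np.linspace(0, 20, 50)) >= 0.0)
        assert np.all(model(np.linspace(0, 20, 50)) <= 1.0)

    def test_invalid_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_parent_fraction([(1.0, 0.5)])
        with pytest.raises(ValueError):
            fit_parent_fraction([(1.0, 0.5), (10.0, 1.2)])
        with pytest.raises(ValueError):
            ParentFractionCurve((1.0, 1.0), (0.9, 0.8))

    def test_parent_fraction_csv_round_trip(self, tmp_path):
        curve = ParentFractionCurve((1.0, 10.0, 30.0), (0.95, 0.72, 0.53), "WT-saline")
        path = tmp_path / "pf.csv"
        curve.to_csv(path)
        back = ParentFractionCurve.from_csv(path, group="WT-saline")
        assert back.fractions == curve.fractions


class TestWholeBloodToPlasma:
    def test_unit_ratio_is_identity(self):
        tac = _tac([5.0] * 4, [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(whole_blood_to_plasma(tac, 1.0).values, tac.values)

    def test_published_factor_scales_values(self):
        tac = _tac([5.0] * 3, np.full(3, 10.0))
        np.testing.assert_allclose(whole_blood_to_plasma(tac, 0.64).values, 6.4)

    def test_round_trip_with_reciprocal(self):
        # both factors must respect the (0, 1.5] contract, so use 0.8 <-> 1.25
        tac = _tac([5.0] * 3, [1.0, 5.0, 2.0])
        back = whole_blood_to_plasma(whole_blood_to_plasma(tac, 0.8), 1.25)
        np.testing.assert_allclose(back.values, tac.values, rtol=1e-12)

    @pytest.mark.parametrize("ratio", [0.0, -0.5, 2.0])
    def test_out_of_range_ratio_rejected(self, ratio):
        with pytest.raises(ValueError):
            whole_blood_to_plasma(_tac([5.0] * 3, [1.0, 1.0, 1.0]), ratio)


class TestMetaboliteCorrection:
    def test_unit_fraction_preserves_frame_averages(self, wt1_curves):
        tac = wt1_curves["wb_tac"]
        model = fit_parent_fraction([(1.0, 1.0), (30.0, 1.0)])
        out = apply_metabolite_correction(tac, model)
        rebinned = pk.bin_frames(out.times_s, out.values, tac.schedule)
        # exact up to the 0.5-s trapezoid quadrature of the fine samples
        np.testing.assert_allclose(
            rebinned.values, tac.values, atol=0.005 * tac.values.max()
        )

    def test_constant_plasma_with_half_fraction(self):
        tac = _tac([5.0] * 8, np.full(8, 10.0))
        model = fit_parent_fraction([(1.0, 0.5), (30.0, 0.5)])
        out = apply_metabolite_correction(tac, model)
        # beyond the 1-min sample the fraction is exactly 0.5
        np.testing.assert_allclose(out.values[out.times_s >= 60.0], 5.0)

    def test_group_table_scales_late_times_by_measured_fraction(self):
        sched = FrameSchedule.from_durations([60.0] * 32)
        tac = TimeActivityCurve(sched, np.full(32, 10.0))
        model = fit_parent_fraction(pk.reference.PARENT_FRACTIONS["WT-saline"])
        out = apply_metabolite_correction(tac, model)
        at_30min = np.interp(1800.0, out.times_s, out.values)
        assert at_30min == pytest.approx(10.0 * 0.53, rel=1e-6)

    def test_scalar_and_metabolite_corrections_commute(self, wt1_curves):
        tac = wt1_curves["wb_tac"]
        model = fit_parent_fraction(pk.reference.PARENT_FRACTIONS["KO"])
        a = apply_metabolite_correction(whole_blood_to_plasma(tac, 0.64), model)
        b = apply_metabolite_correction(tac, model)
        np.testing.assert_allclose(a.values, b.values * 0.64, rtol=1e-12)

    def test_integral_preserving_resample_reproduces_frame_averages(self, wt1_curves):
        tac = wt1_curves["wb_tac"]
        t, vals = resample_to_fine(tac, method="integral-preserving")
        rebinned = pk.bin_frames(t, vals, tac.schedule)
        # exact up to the 0.5-s trapezoid quadrature of the fine samples
        assert np.max(np.abs(rebinned.values - tac.values)) / tac.values.max() < 0.005

    def test_midpoint_resample_hits_midpoints(self, wt1_curves):
        tac = wt1_curves["wb_tac"]
        t, vals = resample_to_fine(tac, method="midpoint")
        np.testing.assert_allclose(
            np.interp(tac.midpoints_s, t, vals), tac.values, rtol=1e-9
        )


class TestAgreementMetrics:
    def test_identical_curves_give_zero(self, wt1_curves):
        tac = wt1_curves["wb_tac"]
        assert auc_percent_difference(tac, tac) == 0.0
        assert k1k2_error_percent(0.4, 0.4) == 0.0

    def test_proportional_curves_give_the_scaling(self, wt1_curves):
        tac = wt1_curves["wb_tac"]
        scaled = tac.with_values(tac.values * 1.035)
        assert auc_percent_difference(scaled, tac) == pytest.approx(3.5)

    def test_hand_computed_aucs(self):
        a = _tac([10.0], [4.1])  # AUC 41
        b = _tac([10.0], [4.0])  # AUC 40
        assert auc_percent_difference(a, b) == pytest.approx(2.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_auc_difference_is_scale_invariant(self, factor):
        a = _tac([5.0, 5.0], [2.0, 3.0])
        b = _tac([5.0, 5.0], [2.5, 2.5])
        base = auc_percent_difference(a, b)
        scaled = auc_percent_difference(
            a.with_values(a.values * factor), b.with_values(b.values * factor)
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_k1k2_error_examples(self):
        assert k1k2_error_percent(0.426, 0.400) == pytest.approx(6.5)
        assert k1k2_error_percent(0.2, 0.4) == pytest.approx(50.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            k1k2_error_percent(0.4, 0.0)

    def test_disjoint_spans_rejected(self):
        a = _tac([5.0] * 3, [1.0] * 3)
        b = TimeActivityCurve(
            FrameSchedule.from_durations([5.0] * 3, t0=100.0), [1.0] * 3
        )
        with pytest.raises(ValueError):
            auc_percent_difference(a, b)
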