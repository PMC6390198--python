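"""VSDI quantification pipeline."""

import dataclasses

import numpy as np
import pytest

from entophys.config import AnalysisConfig
from entophys.exceptions import (
    DimensionMismatchError,
    EmptyROIError,
    UndefinedPPRError,
)
from entophys.vsdi import (
    DffMovie,
    ROISpec,
    VSDIMovie,
    activated_area,
    average_trials,
    compute_dff,
    filter_movie,
    paired_pulse_ratio,
    roi_integral,
    stripe_profile,
)


def make_movie(frames, stim_frame=50, n_baseline=50, stim_frames=()):
    return VSDIMovie(frames=np.asarray(frames, dtype=float),
                     frame_interval_ms=1.0, stim_frame=stim_frame,
                     n_baseline_frames=n_baseline,
                     stim_frames=tuple(stim_frames))


def make_dff(values, stim_frame=50, stim_frames=()):
    values = np.asarray(values, dtype=float)
    return DffMovie(values=values, frame_interval_ms=1.0,
                    stim_frame=stim_frame, n_baseline_frames=50,
                    stim_frames=tuple(stim_frames) or (stim_frame,))


class TestAverageTrials:
    def test_identical_trials_average_to_themselves(self):
        m = make_movie(np.full((10, 10, 100), 500.0))
        avg = average_trials([m] * 8)
        assert np.allclose(avg.frames, m.frames)

    def test_paired_perturbations_cancel(self):
        base = np.full((10, 10, 100), 500.0)
        pert = np.random.default_rng(0).normal(0, 5, base.shape)
        avg = average_trials([make_movie(base + pert),
                              make_movie(base - pert)])
        assert np.allclose(avg.frames, base, atol=1e-10)

    def test_noise_shrinks_as_sqrt_of_trials(self):
        rng = np.random.default_rng(1)
        base = np.full((100, 100, 60), 1000.0)
        sigma = 4.0
        trials = [make_movie(base + rng.normal(0, sigma, base.shape))
                  for _ in range(8)]
        avg = average_trials(trials)
        resid = avg.frames - base
        assert np.std(resid) == pytest.approx(sigma / np.sqrt(8), rel=0.1)

    def test_geometry_mismatch_is_rejected(self):
        with pytest.raises(DimensionMismatchError):
            average_trials([make_movie(np.full((10, 10, 100), 1.0)),
                            make_movie(np.full((10, 11, 100), 1.0))])


class TestDff:
    def test_constant_movie_maps_to_zero(self):
        dff = compute_dff(make_movie(np.full((5, 5, 100), 800.0)))
        assert np.allclose(dff.values, 0.0)

    def test_dye_dimming_maps_to_positive_dff(self):
        """F0 = 1000 with a dip to 998 reads +0.2 % after the sign flip."""
        frames = np.full((2, 2, 100), 1000.0)
        frames[:, :, 60] = 998.0
        dff = compute_dff(make_movie(frames))
        assert dff.values[0, 0, 60] == pytest.approx(0.2, rel=1e-9)

    def test_global_intensity_scaling_is_invariant(self):
        rng = np.random.default_rng(2)
        frames = 1000.0 + rng.uniform(-5, 5, (6, 6, 120))
        a = compute_dff(make_movie(frames))
        b = compute_dff(make_movie(2.0 * frames))
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_baseline_window_has_zero_mean_per_pixel(self):
        rng = np.random.default_rng(3)
        frames = 1000.0 + rng.normal(0, 3, (6, 6, 120))
        dff = compute_dff(make_movie(frames))
        base = dff.values[:, :, :50].mean(axis=2)
        assert np.max(np.abs(base)) < 1e-10


class TestFilter:
    def test_constant_movie_is_unchanged(self):
        dff = make_dff(np.full((9, 9, 60), 0.3))
        out = filter_movie(dff)
        assert np.allclose(out.values, 0.3)

    def test_cubic_time_course_is_preserved_exactly(self):
        t = np.arange(60, dtype=float)
        poly = 0.001 * t**3 - 0.05 * t**2 + 0.2 * t
        values = np.tile(poly, (9, 9, 1))
        out = filter_movie(make_dff(values))
        # an order-3 local fit reproduces a cubic exactly away from the
        # reflected edges
        inner = out.values[4, 4, 3:-3]
        assert np.allclose(inner, poly[3:-3], atol=1e-9)

    def test_spatial_impulse_spreads_over_the_kernel_footprint(self):
        values = np.zeros((9, 9, 9))
        values[4, 4, :] = 9.0
        out = filter_movie(make_dff(values, stim_frame=5))
        assert out.values[4, 4, 4] == pytest.approx(1.0)
        assert out.values[3, 4, 4] == pytest.approx(1.0)
        assert out.values[2, 4, 4] == pytest.approx(0.0, abs=1e-12)

    def test_oversized_kernel_is_rejected(self):
        cfg = AnalysisConfig()
        cfg.vsdi.temporal_window = 99
        with pytest.raises(DimensionMismatchError):
            filter_movie(make_dff(np.zeros((9, 9, 60))), cfg)


class TestROIIntegral:
    def _roi(self):
        return ROISpec(rois={"blob": np.array([[1, 1], [1, 2]])})

    def test_zero_trace_integrates_to_zero(self):
        assert roi_integral(make_dff(np.zeros((5, 5, 200))),
                            self._roi(), "blob") == 0.0

    def test_rectangular_response_has_hand_computed_area(self):
        """0.1 % lasting 100 ms integrates to ~10 %*ms (trapezoid edges)."""
        values = np.zeros((5, 5, 300))
        values[:, :, 100:200] = 0.1
        got = roi_integral(make_dff(values), self._roi(), "blob")
        assert got == pytest.approx(10.0, rel=0.02)

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(4)
        values = np.abs(rng.normal(0, 0.1, (5, 5, 300)))
        a = roi_integral(make_dff(values), self._roi(), "blob")
        b = roi_integral(make_dff(2 * values), self._roi(), "blob")
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_additive_over_disjoint_windows(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 0.1, (5, 5, 300))
        total = roi_integral(make_dff(values), self._roi(), "blob",
                             window=(50, 300))
        left = roi_integral(make_dff(values), self._roi(), "blob",
                            window=(50, 150))
        right = roi_integral(make_dff(values), self._roi(), "blob",
                             window=(149, 300))
        # trapezoid split shares the boundary sample
        assert total == pytest.approx(left + right, rel=0.05)

    def test_empty_roi_is_rejected(self):
        with pytest.raises(EmptyROIError):
            roi_integral(make_dff(np.zeros((5, 5, 100))),
                         ROISpec(rois={"none": np.empty((0, 2), int)}),
                         "none")


class TestActivatedArea:
    def test_blank_movie_activates_nothing(self):
        assert activated_area(make_dff(np.zeros((20, 20, 100)))) == 0

    def test_constructed_scene_counts_exactly(self):
        values = np.zeros((50, 50, 100))
        rng = np.random.default_rng(6)
        rows = rng.choice(50 * 50, size=200, replace=False)
        for flat in rows:
            values[flat // 50, flat % 50, 70] = 0.1
        assert activated_area(make_dff(values)) == 200

    def test_threshold_is_strict(self):
        values = np.zeros((5, 5, 100))
        values[0, 0, 60] = 0.05   # exactly at threshold: not counted
        values[1, 1, 60] = 0.0501
        assert activated_area(make_dff(values)) == 1

    def test_monotone_in_amplitude_and_threshold(self):
        rng = np.random.default_rng(7)
        values = np.abs(rng.normal(0, 0.04, (30, 30, 80)))
        dff = make_dff(values)
        a1 = activated_area(dff)
        a2 = activated_area(make_dff(2 * values))
        assert a2 >= a1
        assert activated_area(dff, threshold=0.1) <= a1


class TestPPR:
    def _paired(self, amp1, amp2, s1=50, s2=75):
        values = np.zeros((5, 5, 200))
        values[:, :, s1 + 2] = amp1
        values[:, :, s2 + 2] = amp2
        return make_dff(values, stim_frame=s1, stim_frames=(s1, s2))

    def test_identical_pulses_give_unity(self):
        res = paired_pulse_ratio(
            self._paired(0.05, 0.05),
            ROISpec(rois={"exposed_blade": np.array([[2, 2]])}))
        assert res.mean == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_depression(self):
        """Amplitudes 0.05 then 0.04 give a ratio of 0.8."""
        res = paired_pulse_ratio(
            self._paired(0.05, 0.04),
            ROISpec(rois={"exposed_blade": np.array([[2, 2]])}))
        assert res.mean == pytest.approx(0.8, abs=1e-9)

    def test_zero_first_pulse_is_undefined(self):
        with pytest.raises(UndefinedPPRError):
            paired_pulse_ratio(
                self._paired(0.0, 0.05),
                ROISpec(rois={"exposed_blade": np.array([[2, 2]])}))


class TestStripe:
    def test_uniform_response_is_flat(self):
        values = np.zeros((20, 20, 100))
        values[:, :, 60:] = 0.2
        rois = ROISpec.stripe_from_segment((0, 0), (0, 15), (20, 20))
        prof = stripe_profile(make_dff(values), rois)
        assert np.allclose(prof[:, 1], 0.2)

    def test_gaussian_falloff_matches_the_generating_profile(self):
        sigma = 4.0
        rows, cols = np.mgrid[0:20, 0:20].astype(float)
        amp = 0.5 * np.exp(-(rows**2 + cols**2) / (2 * sigma**2))
        values = np.zeros((20, 20, 100))
        values[:, :, 70] = amp
        rois = ROISpec.stripe_from_segment((0, 0), (0, 19), (20, 20))
        prof = stripe_profile(make_dff(values), rois)
        expected = 0.5 * np.exp(-prof[:, 0] ** 2 / (2 * sigma**2))
        assert np.allclose(prof[:, 1], expected, atol=1e-9)

    def test_monotone_scene_yields_strictly_decreasing_profile(self):
        values = np.zeros((20, 20, 100))
        for cc in range(20):
            values[0, cc, 60] = 1.0 / (1.0 + cc)
        rois = ROISpec.stripe_from_segment((0, 0), (0, 19), (20, 20))
        prof = stripe_profile(make_dff(values), rois)
        assert np.all(np.diff(prof[:, 1]) < 0)

    def test_out_of_bounds_stripe_is_truncated(self):
        rois = ROISpec.stripe_from_segment((0, 0), (0, 40), (20, 20))
        assert rois.stripe[:, 1].max() == 19
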