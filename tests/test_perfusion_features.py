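"""Milestone feature extraction: smoothing, peaks, half-rise, slopes,
moments, centre of mass and the assembled feature vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgdyn import perfusion_features as pf
from icgdyn.errors import InvalidParameterError, UndefinedFeatureError
from icgdyn.trace_extraction import ROITrace

from conftest import make_trace


class TestSmoothing:
    def test_zero_window_identity(self, trace_factory):
        tr = trace_factory(np.random.default_rng(0).uniform(0, 255, 100))
        out = pf.smooth_trace(tr, 0.0)
        assert np.array_equal(out.intensities, tr.intensities)

    def test_constant_unchanged(self, trace_factory):
        tr = trace_factory(np.full(100, 7.0))
        assert np.allclose(pf.smooth_trace(tr, 1.0).intensities, 7.0)

    def test_impulse_spread(self, trace_factory):
        h, k = 90.0, 5
        v = np.zeros(101)
        v[50] = h
        tr = trace_factory(v, fps=1.0)
        out = pf.smooth_trace(tr, float(k))  # window covers k samples
        assert out.intensities[50] == pytest.approx(h / k)

    def test_negative_window_rejected(self, trace_factory):
        with pytest.raises(InvalidParameterError):
            pf.smooth_trace(trace_factory(np.zeros(10)), -1.0)


class TestPeakMilestones:
    def test_monotone_trace_peaks_at_end(self, trace_factory):
        tr = trace_factory(np.linspace(0, 200, 300))
        tmax, fmax, f_end = pf.peak_milestones(tr, smooth_window_s=0.0)
        assert tmax == tr.times[-1]
        assert fmax == f_end == 200.0

    def test_tie_breaks_to_earliest(self, trace_factory):
        v = np.zeros(120)
        v[30] = v[80] = 100.0
        tr = trace_factory(v)
        tmax, _, _ = pf.peak_milestones(tr, smooth_window_s=0.0)
        assert tmax == tr.times[30]


class TestHalfTime:
    def test_linear_ramp_ratio_half(self, trace_factory):
        tr = trace_factory(np.linspace(0, 150, 900))  # 30 s ramp at 30 fps
        _, ratio = pf.half_time_and_ratio(tr, smooth_window_s=0.0)
        assert ratio == pytest.approx(0.5, abs=0.02)

    def test_instant_step_degenerate_limit(self, trace_factory):
        """For an instantaneous step the half-rise collapses onto the peak:
        t_half and tmax differ by at most one sample interval."""
        v = np.zeros(900)
        v[300:] = 100.0  # step at 10 s
        tr = trace_factory(v)
        t_half, ratio = pf.half_time_and_ratio(tr, smooth_window_s=0.0)
        tmax, _, _ = pf.peak_milestones(tr, smooth_window_s=0.0)
        assert 0 < ratio <= 1.0
        assert abs(tmax - t_half) <= 1.0 / tr.fps

    def test_flat_trace_undefined(self, trace_factory):
        with pytest.raises(UndefinedFeatureError):
            pf.half_time_and_ratio(trace_factory(np.full(300, 9.0)))


class TestUpslope:
    def test_linear_ramp_recovers_slope(self, trace_factory):
        m = 5.0  # g.u./s
        times = np.arange(900) / 30.0
        tr = trace_factory(m * times)
        assert pf.upslope(tr, smooth_window_s=0.0) == pytest.approx(m, rel=1e-6)

    def test_step_bounded_by_sample_interval(self, trace_factory):
        v = np.zeros(300)
        v[150:] = 120.0
        tr = trace_factory(v)
        up = pf.upslope(tr, smooth_window_s=0.0)
        assert up <= 120.0 / (1 / 30.0) + 1e-6

    def test_flat_trace_errors(self, trace_factory):
        with pytest.raises(UndefinedFeatureError):
            pf.upslope(trace_factory(np.full(300, 50.0)))


class TestReferencePeak:
    def test_single_trace(self, trace_factory):
        v = np.zeros(1200)
        v[720] = 100.0  # peak at 24 s
        rp = pf.reference_peak([trace_factory(v)], smooth_window_s=0.0)
        assert rp.t_star == pytest.approx(24.0)
        assert rp.provenance == "single_crlm_peak"

    def test_mean_of_two(self, trace_factory):
        v1 = np.zeros(1200); v1[600] = 100.0  # 20 s
        v2 = np.zeros(1200); v2[900] = 100.0  # 30 s
        rp = pf.reference_peak([trace_factory(v1), trace_factory(v2)],
                               smooth_window_s=0.0)
        assert rp.t_star == pytest.approx(25.0)
        assert rp.provenance == "mean_crlm_peaks"

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            pf.reference_peak([])


class TestSlopes:
    def test_delta_is_ten_times_slope(self, trace_factory):
        rng = np.random.default_rng(3)
        tr = trace_factory(np.clip(100 + np.cumsum(rng.normal(0, 1, 1200)), 0, 255))
        d = pf.delta_after(tr, 5.0, 10.0)
        s = pf.slope_after(tr, 5.0, 10.0)
        assert d == pytest.approx(10.0 * s, abs=1e-12)

    def test_constant_trace_zero_slope(self, trace_factory):
        tr = trace_factory(np.full(900, 80.0))
        assert pf.slope_after(tr, 2.0, 10.0) == 0.0

    def test_out_of_window_errors(self, trace_factory):
        tr = trace_factory(np.full(300, 80.0))  # 10 s trace
        with pytest.raises(UndefinedFeatureError):
            pf.slope_after(tr, 5.0, 10.0)


class TestComAndMoments:
    def test_constant_trace_com_is_mean_time(self, trace_factory):
        tr = trace_factory(np.full(2700, 10.0))
        assert pf.centre_of_mass(tr) == pytest.approx(tr.times.mean())

    def test_single_mass_point(self, trace_factory):
        v = np.zeros(900)
        v[300] = 55.0  # t = 10 s
        assert pf.centre_of_mass(trace_factory(v)) == pytest.approx(10.0)

    def test_all_zero_undefined(self, trace_factory):
        with pytest.raises(UndefinedFeatureError):
            pf.centre_of_mass(trace_factory(np.zeros(100)))

    def test_symmetric_values_zero_skew(self, trace_factory):
        tr = trace_factory(np.array([1.0, 2.0, 3.0, 2.0]))
        skew, _ = pf.shape_moments(tr)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_g1_hand_computation(self, trace_factory):
        # {0,0,0,10}: m2 = 18.75, m3 = 93.75 -> g1 = 2/sqrt(3)
        skew, _ = pf.shape_moments(trace_factory(np.array([0.0, 0.0, 0.0, 10.0])))
        assert skew == pytest.approx(2.0 / np.sqrt(3.0), rel=1e-12)

    def test_saturating_curve_negative_skew(self, trace_factory):
        """A curve that saturates early spends most samples near its
        maximum: mass at high values, tail toward low early values."""
        times = np.arange(2700) / 30.0
        tr = trace_factory(20 + 180 * (1 - np.exp(-times / 8.0)))
        skew, _ = pf.shape_moments(tr)
        assert skew < 0

    def test_calibrated_lesion_curve_negative_skew(self, calibrated, trace_factory):
        from icgdyn.synth_scene.kinetics import perfusion_curve

        times = np.arange(2700) / 30.0
        tr = trace_factory(perfusion_curve(times, calibrated["crlm"]))
        skew, _ = pf.shape_moments(tr)
        assert skew < 0

    def test_zero_variance_undefined(self, trace_factory):
        with pytest.raises(UndefinedFeatureError):
            pf.shape_moments(trace_factory(np.full(10, 4.0)))


class TestComputeFeatures:
    def test_full_vector_and_identity(self, calibrated):
        from icgdyn.synth_scene.kinetics import perfusion_curve

        times = np.arange(2700) / 30.0
        tr = ROITrace(times=times,
                      intensities=perfusion_curve(times, calibrated["crlm"]),
                      fps=30.0, label="crlm", roi_id="c")
        f = pf.compute_features(tr)
        assert f.delta10 == pytest.approx(10.0 * f.slope10, abs=1e-12)
        vals = f.as_series()[list(pf.FEATURE_ORDER)] if hasattr(pf, "FEATURE_ORDER") else None
        for name in ("tmax", "fmax", "f_end", "upslope", "time_ratio", "delta10",
                     "slope10", "slope20", "slope60", "kurtosis", "skew", "com"):
            assert np.isfinite(getattr(f, name)), name

    def test_healthy_uses_mapped_reference(self, calibrated):
        from icgdyn.synth_scene.kinetics import perfusion_curve

        times = np.arange(2700) / 30.0
        tr = ROITrace(times=times,
                      intensities=perfusion_curve(times, calibrated["healthy"]),
                      fps=30.0, label="healthy", roi_id="h")
        f = pf.compute_features(tr, t_star=24.0)
        assert f.reference_time == 24.0
        assert f.slope10 > 0  # still rising at the mapped lesion peak

    def test_short_trace_missing_slope60(self, trace_factory):
        times = np.arange(900) / 30.0  # 30 s
        v = np.clip(200 * np.exp(-0.5 * (times - 5) ** 2), 0, 255) + 5
        tr = trace_factory(v)
        f = pf.compute_features(tr)
        assert np.isnan(f.slope60)
        assert np.isfinite(f.slope10)

    def test_time_shift_invariance(self, calibrated):
        """Features depend on time relative to the window start only."""
        from icgdyn.synth_scene.kinetics import perfusion_curve

        times = np.arange(2700) / 30.0
        v = perfusion_curve(times, calibrated["crlm"])
        a = pf.compute_features(make_trace(v))
        shifted = ROITrace(times=times + 1234.5, intensities=v, fps=30.0,
                           label="crlm", roi_id="t")
        b = pf.compute_features(shifted)
        assert b.tmax == pytest.approx(a.tmax, abs=1e-9)
        assert b.com == pytest.approx(a.com, abs=1e-6)
        assert b.time_ratio == pytest.approx(a.time_ratio, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=1.8))
    def test_intensity_scaling_property(self, c):
        """Scaling intensities by c scales amplitudes/slopes by c and leaves
        time-valued and shape features unchanged."""
        rng = np.random.default_rng(17)
        times = np.arange(1200) / 30.0
        base = 10 + 90 * np.exp(-0.5 * ((times - 12) / 5) ** 2) + rng.normal(0, 0.5, 1200)
        base = np.clip(base, 0, 255 / 2)
        a = pf.compute_features(make_trace(base))
        b = pf.compute_features(make_trace(np.clip(c * base, 0, 255)))
        assert b.fmax == pytest.approx(c * a.fmax, rel=1e-9)
        assert b.delta10 == pytest.approx(c * a.delta10, rel=1e-6, abs=1e-9)
        assert b.upslope == pytest.approx(c * a.upslope, rel=1e-6)
        assert b.tmax == a.tmax
        assert b.time_ratio == pytest.approx(a.time_ratio, rel=1e-9)
        assert b.com == pytest.approx(a.com, rel=1e-12)
        assert b.skew == pytest.approx(a.skew, rel=1e-9)
        assert b.kurtosis == pytest.approx(a.kurtosis, rel=1e-9)


class TestFeatureTable:
    def test_cohort_table_layout(self, cohort_table):
        assert cohort_table["roi_id"].is_unique
        assert set(cohort_table["label"]) == {"crlm", "healthy", "benign_cyst"}
        assert len(cohort_table) == 162

    def test_milestone_recovery_against_generator_truth(self, cohort_table):
        """Mean extracted features track the generator's own per-ROI
        milestone draws (2 SEM)."""
        crlm = cohort_table[cohort_table.label == "crlm"]
        for col, target in (("tmax", 23.931), ("fmax", 123.594)):
            vals = crlm[col].dropna()
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - target) < max(2 * sem, 0.05 * target)
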