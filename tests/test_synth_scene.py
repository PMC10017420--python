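"""Kinetic curve family, milestone calibration, scene rendering and
microscopy section generation."""

import numpy as np
import pytest

from icgdyn import perfusion_features as pf
from icgdyn.errors import CalibrationError, InvalidParameterError
from icgdyn.reference import REFERENCE_MILESTONES
from icgdyn.synth_scene import (
    KineticParams,
    SceneConfig,
    SectionConfig,
    calibrate_kinetics,
    gamma_variate,
    perfusion_curve,
    render_microscopy_section,
    render_sequence,
    sample_roi_milestones,
    simulate_roi_traces,
    solve_kinetics,
)
from icgdyn.trace_extraction import ROITrace


class TestGammaVariate:
    P = KineticParams(baseline=0.0, arrival_delay=0.0, time_to_peak=20.0,
                      amplitude=100.0, shape=3.0)

    @pytest.mark.parametrize(
        "t,expected",
        [
            (20.0, 100.0),  # peak value by construction
            (0.0, 0.0),  # pre-arrival baseline
            (40.0, 100.0 * 8.0 * np.exp(-3.0)),  # direct evaluation: 39.83
        ],
    )
    def test_pointwise_values(self, t, expected):
        assert gamma_variate(t, self.P) == pytest.approx(expected, abs=1e-9)

    def test_baseline_before_arrival_and_peak_exact(self):
        p = KineticParams(baseline=12.0, arrival_delay=5.0, time_to_peak=15.0,
                          amplitude=80.0, shape=2.2)
        t = np.linspace(0, 5, 50)
        assert np.allclose(gamma_variate(t, p), 12.0)
        assert gamma_variate(p.peak_time, p) == pytest.approx(92.0)

    def test_unimodal(self):
        p = KineticParams(baseline=5.0, arrival_delay=2.0, time_to_peak=20.0,
                          amplitude=100.0, shape=1.2, retention=0.6)
        t = np.arange(0, 90, 0.05)
        v = perfusion_curve(t, p)
        i = np.argmax(v)
        assert np.all(np.diff(v[: i + 1]) >= -1e-9)
        assert np.all(np.diff(v[i:]) <= 1e-9)

    def test_retention_plateau_continuity(self):
        p = KineticParams(baseline=5.0, arrival_delay=2.0, time_to_peak=20.0,
                          amplitude=100.0, shape=1.2, retention=0.7)
        eps = 1e-6
        before = perfusion_curve(p.peak_time - eps, p)
        after = perfusion_curve(p.peak_time + eps, p)
        assert after == pytest.approx(before, abs=1e-3)
        assert perfusion_curve(1e4, p) == pytest.approx(5.0 + 0.7 * 100.0, rel=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(time_to_peak=0.0), dict(time_to_peak=-3.0), dict(shape=0.0),
        dict(shape=-1.0), dict(amplitude=-5.0), dict(retention=1.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(baseline=0.0, arrival_delay=0.0, time_to_peak=20.0,
                      amplitude=100.0, shape=3.0)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            KineticParams(**kwargs)


class TestCalibration:
    def test_crlm_peak_time_recovered(self, calibrated):
        p = calibrated["crlm"]
        times = np.arange(2700) / 30.0
        trace = ROITrace(times=times, intensities=perfusion_curve(times, p),
                         fps=30.0, label="crlm", roi_id="c")
        tmax, fmax, _ = pf.peak_milestones(trace)
        assert tmax == pytest.approx(23.931, abs=0.5)
        assert fmax == pytest.approx(123.594, rel=0.02)

    def test_healthy_peak_time_recovered(self, calibrated):
        p = calibrated["healthy"]
        times = np.arange(2700) / 30.0
        trace = ROITrace(times=times, intensities=perfusion_curve(times, p),
                         fps=30.0, label="healthy", roi_id="h")
        tmax, _, f_end = pf.peak_milestones(trace)
        assert tmax == pytest.approx(82.616, abs=0.5)
        assert f_end == pytest.approx(188.988, rel=0.02)

    def test_crlm_time_ratio_recovered(self, calibrated):
        p = calibrated["crlm"]
        times = np.arange(2700) / 30.0
        trace = ROITrace(times=times, intensities=perfusion_curve(times, p),
                         fps=30.0, label="crlm", roi_id="c")
        _, ratio = pf.half_time_and_ratio(trace)
        assert ratio == pytest.approx(0.341, abs=0.02)

    def test_flat_target_raises(self):
        with pytest.raises(CalibrationError):
            solve_kinetics(tmax=20.0, fmax=8.0, f_end=8.0, baseline=8.0)

    def test_missing_required_target_raises(self):
        with pytest.raises(InvalidParameterError):
            calibrate_kinetics({"crlm": {"tmax": 24.0, "fmax": 120.0}})

    def test_deterministic(self):
        a = calibrate_kinetics()
        b = calibrate_kinetics()
        assert a == b


class TestMilestoneSampling:
    def test_mean_matching_under_truncation(self):
        rng = np.random.default_rng(0)
        draws = sample_roi_milestones("crlm", 4000, rng)
        ref = REFERENCE_MILESTONES["crlm"]
        assert draws["tmax"].mean() == pytest.approx(ref["tmax"][0], rel=0.03)
        assert draws["fmax"].mean() == pytest.approx(ref["fmax"][0], rel=0.03)
        assert draws["time_ratio"].mean() == pytest.approx(ref["time_ratio"][0], rel=0.03)
        assert draws["fmax"].max() <= 250.0

    def test_class_separation_effect_size(self):
        """Per-ROI Tmax separates lesion from parenchyma at > 3 pooled SDs."""
        rng = np.random.default_rng(1)
        crlm = sample_roi_milestones("crlm", 500, rng)["tmax"]
        healthy = sample_roi_milestones("healthy", 500, rng)["tmax"]
        pooled = np.sqrt((crlm.var(ddof=1) + healthy.var(ddof=1)) / 2)
        d = abs(healthy.mean() - crlm.mean()) / pooled
        assert d > 3.0

    def test_unknown_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_roi_milestones("spleen", 5, np.random.default_rng(0))

    def test_trace_simulation_deterministic_and_bounded(self):
        a = simulate_roi_traces("crlm", 5, 7)
        b = simulate_roi_traces("crlm", 5, 7)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.intensities, tb.intensities)
            assert ta.intensities.min() >= 0 and ta.intensities.max() <= 255


class TestRenderSequence:
    def test_zero_motion_zero_noise_matches_model(self, static_pair):
        pair, gt = static_pair
        for name in ("lesion", "healthy"):
            mask = gt.class_map.mask(name)
            r, c = map(lambda a: a[0], np.where(mask))
            curve = perfusion_curve(pair.timestamps, gt.kinetics[name])
            err = np.abs(pair.nir[:, r, c].astype(float) - curve)
            assert err.max() <= 0.5  # 8-bit quantization only

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(height=48, width=64, fps=6.0, duration_s=10.0)
        p1, _ = render_sequence(cfg, seed=11)
        p2, _ = render_sequence(cfg, seed=11)
        assert np.array_equal(p1.nir, p2.nir)
        assert np.array_equal(p1.white, p2.white)

    def test_lesion_peaks_before_healthy(self, static_pair):
        pair, gt = static_pair
        assert (
            gt.kinetics["lesion"].peak_time < gt.kinetics["healthy"].peak_time
        )
        lesion = gt.class_map.mask("lesion")
        healthy = gt.class_map.mask("healthy")
        t_idx_lesion = pair.nir[:, lesion].astype(float).mean(axis=1).argmax()
        t_idx_healthy = pair.nir[:, healthy].astype(float).mean(axis=1).argmax()
        assert t_idx_lesion < t_idx_healthy

    def test_overlay_mode_green_channel_is_nir(self):
        cfg = SceneConfig(height=48, width=64, fps=6.0, duration_s=8.0,
                          overlay_mode=True)
        pair, _ = render_sequence(cfg, seed=2)
        assert pair.white is None and pair.overlay is not None
        assert np.array_equal(pair.overlay[..., 1], pair.nir)

    def test_study_protocol_flag(self):
        assert SceneConfig().meets_study_protocol
        assert not SceneConfig(duration_s=40.0).meets_study_protocol


class TestMicroscopy:
    def test_attenuation_default(self):
        u = render_microscopy_section(stained=False, seed=4)
        s = render_microscopy_section(stained=True, seed=4)
        ratio = u.image.mean() / s.image.mean()
        assert ratio == pytest.approx(6.5, rel=1e-9)

    def test_attenuation_one_identity(self):
        cfg = SectionConfig(attenuation=1.0)
        u = render_microscopy_section(cfg, stained=False, seed=4)
        s = render_microscopy_section(cfg, stained=True, seed=4)
        assert np.array_equal(u.image, s.image)

    def test_zero_lesion_emission(self):
        cfg = SectionConfig(lesion_emission=0.0)
        sec = render_microscopy_section(cfg, seed=0)
        assert sec.image[sec.masks["lesion"]].mean() == 0.0

    def test_healthy_far_brighter_than_lesion(self):
        sec = render_microscopy_section(seed=1)
        h = sec.image[sec.masks["healthy"]].mean()
        l = sec.image[sec.masks["lesion"]].mean()
        assert h / l > 50
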