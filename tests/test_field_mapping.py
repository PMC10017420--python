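"""TPS warps, landmark matching, stabilization, per-pixel maps,
piecewise-constant fitting and clustering."""

import itertools

import numpy as np
import pytest

from icgdyn.errors import (
    DegenerateConfigurationError,
    InsufficientLandmarksError,
    InvalidParameterError,
)
from icgdyn.field_mapping import (
    StabilizationConfig,
    cluster_field,
    detect_and_match,
    fit_tps,
    pixel_milestones,
    pwc_fit,
    pwc_levels,
    render,
    stabilize,
)
from icgdyn.synth_scene import SceneConfig, render_sequence


class TestTps:
    def test_pure_translation_exact(self):
        src = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 0.0], [10.0, 10.0]])
        warp = fit_tps(src, src + [2.0, 5.0], lam=0.0)
        pts = np.random.default_rng(0).uniform(-5, 15, (50, 2))
        assert np.allclose(warp.transform(pts), pts + [2.0, 5.0], atol=1e-9)
        assert np.allclose(warp.weights, 0.0, atol=1e-9)

    def test_identity(self):
        src = np.array([[1.0, 1.0], [1.0, 9.0], [9.0, 5.0], [5.0, 2.0]])
        warp = fit_tps(src, src, lam=0.0)
        pts = np.random.default_rng(1).uniform(0, 10, (20, 2))
        assert np.allclose(warp.transform(pts), pts, atol=1e-9)

    def test_affine_exactness_below_tolerance(self):
        """Affine landmark motion is reproduced to 1e-6 px everywhere."""
        rng = np.random.default_rng(2)
        src = rng.uniform(0, 100, (12, 2))
        A = np.array([[1.02, -0.05], [0.04, 0.98]])
        b = np.array([3.0, -2.0])
        dst = src @ A.T + b
        warp = fit_tps(src, dst, lam=0.0)
        pts = rng.uniform(-20, 120, (200, 2))
        assert np.abs(warp.transform(pts) - (pts @ A.T + b)).max() < 1e-6

    def test_interpolates_bent_point_exactly(self):
        src = np.array([[0.0, 0.0], [0.0, 20.0], [20.0, 0.0], [20.0, 20.0],
                        [10.0, 10.0]])
        dst = src.copy()
        dst[4] += [1.5, -0.8]  # bend only the interior point
        warp = fit_tps(src, dst, lam=0.0)
        assert np.allclose(warp.transform(src), dst, atol=1e-8)
        # the affine component stays near identity; bending is carried by
        # the kernel weights
        assert np.allclose(warp.affine[1:], np.eye(2), atol=0.05)

    def test_against_skimage_oracle(self):
        """Independent cross-check of the warp values at lam = 0."""
        skimage_tps = pytest.importorskip("skimage.transform").ThinPlateSplineTransform
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 50, (8, 2))
        dst = src + rng.normal(0, 2.0, (8, 2))
        ours = fit_tps(src, dst, lam=0.0)
        ref = skimage_tps()
        # skimage uses (x, y) order; ours is (row, col)
        ref.estimate(src[:, ::-1], dst[:, ::-1])
        pts = rng.uniform(0, 50, (40, 2))
        assert np.allclose(ours.transform(pts), ref(pts[:, ::-1])[:, ::-1], atol=1e-4)

    def test_collinear_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(DegenerateConfigurationError):
            fit_tps(src, src + 1.0, lam=0.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            fit_tps(np.zeros((2, 2)), np.zeros((2, 2)))


class TestLandmarks:
    @pytest.fixture(scope="class")
    def textured(self):
        from icgdyn.synth_scene.scene import _white_texture

        return _white_texture(np.random.default_rng(7), 90, 120)

    def test_identical_frames_zero_displacement(self, textured):
        m = detect_and_match(textured, textured)
        assert len(m) >= 6
        assert np.abs(m.displacements).max() < 0.1

    def test_known_translation_recovered(self, textured):
        shifted = np.roll(textured, (3, 0), axis=(0, 1))
        m = detect_and_match(textured, shifted)
        med = np.median(m.displacements, axis=0)
        assert med[0] == pytest.approx(3.0, abs=0.5)
        assert med[1] == pytest.approx(0.0, abs=0.5)

    def test_uniform_frames_rejected(self):
        flat = np.full((80, 80), 0.5)
        with pytest.raises(InsufficientLandmarksError):
            detect_and_match(flat, flat)


class TestPwc:
    def test_step_signal(self):
        bp, levels, sse = pwc_fit([0, 0, 0, 10, 10, 10], 2)
        assert bp == [3]
        assert np.allclose(levels, [0.0, 10.0])
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_single_segment_is_mean(self):
        y = np.array([1.0, 4.0, 2.0, 7.0])
        bp, levels, sse = pwc_fit(y, 1)
        assert bp == []
        assert levels[0] == pytest.approx(y.mean())
        assert sse == pytest.approx(((y - y.mean()) ** 2).sum())

    def test_too_many_segments_rejected(self):
        with pytest.raises(InvalidParameterError):
            pwc_fit([1.0, 2.0], 3)

    @staticmethod
    def brute_force_sse(y, k):
        """Exhaustive search over all contiguous segmentations."""
        n = len(y)
        best = np.inf
        for cuts in itertools.combinations(range(1, n), k - 1):
            bounds = [0, *cuts, n]
            sse = sum(
                float(((y[a:b] - y[a:b].mean()) ** 2).sum())
                for a, b in zip(bounds[:-1], bounds[1:])
            )
            best = min(best, sse)
        return best

    @pytest.mark.parametrize("n,k,seed", [(12, 2, 0), (16, 3, 1), (20, 3, 2),
                                          (18, 4, 3), (20, 4, 4)])
    def test_dp_equals_bruteforce(self, n, k, seed):
        y = np.random.default_rng(seed).normal(0, 1, n)
        _, _, sse = pwc_fit(y, k)
        assert sse == pytest.approx(self.brute_force_sse(y, k), abs=1e-9)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_batched_levels_match_single(self, k):
        rng = np.random.default_rng(5)
        curves = rng.normal(0, 1, (7, 25))
        batched = pwc_levels(curves, k)
        for i, y in enumerate(curves):
            _, levels, _ = pwc_fit(y, k)
            assert np.allclose(batched[i], levels, atol=1e-9)


class TestStabilize:
    def test_zero_motion_scene_passthrough(self, static_pair, static_field):
        pair, _ = static_pair
        field = static_field
        raw = pair.nir[field.source_indices].astype(np.float32)
        assert field.valid.all()
        assert np.abs(field.volume - raw).max() <= 1.0

    def test_residual_below_one_pixel_rms(self, moving_pair, moving_field):
        """Composed warp positions agree with the ground-truth motion record
        to < 1 px RMS over the valid region."""
        pair, gt = moving_pair
        field = moving_field
        H, W = pair.frame_shape
        rr, cc = np.mgrid[0:H, 0:W].astype(float)
        ref_src = field.source_indices[field.reference_index]
        disp_ref = gt.displacement(ref_src)
        world = np.stack([rr, cc]) + disp_ref  # tissue point per ref pixel
        from scipy.ndimage import map_coordinates

        errs = []
        for j, src_idx in enumerate(field.source_indices[::10]):
            pos = int(np.where(field.source_indices == src_idx)[0][0])
            disp_j = gt.displacement(src_idx)
            # invert x + disp_j(x) = world via one smooth-field iteration
            dj_r = map_coordinates(disp_j[0], world, order=1, mode="nearest")
            dj_c = map_coordinates(disp_j[1], world, order=1, mode="nearest")
            true_pos = world - np.stack([dj_r, dj_c])
            est = field.warps[pos]
            err = np.sqrt(((est - true_pos) ** 2).sum(axis=0))
            errs.append(err[field.valid])
        rms = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rms < 1.0

    def test_border_invalidated_interior_valid(self, moving_field):
        field = moving_field
        assert not field.valid.all()
        H, W = field.valid.shape
        assert field.valid[H // 2, W // 2]

    def test_stabilization_improves_peak_time_fidelity(self, moving_pair, moving_field):
        """Per-pixel Tmax error against the ground-truth class kinetics is
        strictly smaller after stabilization than on the raw stack."""
        pair, gt = moving_pair
        field = moving_field
        raw_vol = pair.nir[field.source_indices].astype(np.float32)

        true_tmax = np.zeros(field.valid.shape)
        for name in ("lesion", "rim", "healthy", "background"):
            m = gt.class_map.mask(name)
            true_tmax[m] = min(gt.kinetics[name].peak_time, field.times[-1])

        def tmax_map(vol):
            from icgdyn.field_mapping.maps import _smooth_axis0

            sm = _smooth_axis0(vol, int(round(field.fps)))
            return field.times[np.argmax(sm, axis=0)]

        sel = field.valid
        err_stab = np.abs(tmax_map(field.volume) - true_tmax)[sel].mean()
        err_raw = np.abs(tmax_map(raw_vol) - true_tmax)[sel].mean()
        assert err_stab < err_raw


class TestMaps:
    def test_shared_curve_gives_constant_maps(self):
        from icgdyn.field_mapping.stabilize import StabilizedField

        T, H, W = 160, 10, 12
        times = np.arange(T) / 7.0
        curve = 10 + 100 * np.exp(-0.5 * ((times - 3) / 1.5) ** 2)
        vol = np.tile(curve[:, None, None], (1, H, W)).astype(np.float32)
        field = StabilizedField(volume=vol, times=times,
                                valid=np.ones((H, W), bool), reference_index=0,
                                fps=7.0, source_indices=np.arange(T))
        com, slope = pixel_milestones(field)
        assert np.nanstd(com) < 1e-5
        assert np.nanstd(slope) < 1e-5

    def test_lesion_maps_ordering(self, static_pair, static_field):
        """Lesion pixels: earlier COM and negative outflow; parenchyma:
        later COM and non-negative outflow."""
        pair, gt = static_pair
        field = static_field
        com, slope = pixel_milestones(field)
        lesion = gt.class_map.mask("lesion") & field.valid
        healthy = gt.class_map.mask("healthy") & field.valid
        assert np.nanmean(com[lesion]) < np.nanmean(com[healthy])
        assert np.nanmean(slope[lesion]) < 0
        h_slopes = slope[healthy]
        assert np.nanmean(h_slopes) >= 0 or np.isnan(h_slopes).all()

    def test_cluster_recovers_lesion(self, static_pair, static_field):
        pair, gt = static_pair
        field = static_field
        labels = cluster_field(field, k=3, seed=0, feature_mode="pwc",
                               n_segments=5)
        lesion = gt.class_map.mask("lesion") & field.valid
        best = max(
            range(3),
            key=lambda c: ((labels == c) & lesion).sum()
            / max(((labels == c) | lesion).sum(), 1),
        )
        inter = ((labels == best) & lesion).sum()
        union = ((labels == best) | lesion).sum()
        assert inter / union >= 0.8

    def test_cluster_deterministic(self, static_field):
        field = static_field
        a = cluster_field(field, k=3, seed=4, feature_mode="milestones")
        b = cluster_field(field, k=3, seed=4, feature_mode="milestones")
        assert np.array_equal(a, b)

    def test_identical_curves_flagged(self):
        from icgdyn.field_mapping.stabilize import StabilizedField

        T, H, W = 120, 6, 6
        times = np.arange(T) / 7.0
        curve = 10 + 50 * np.exp(-0.5 * ((times - 2) / 1.0) ** 2)
        vol = np.tile(curve[:, None, None], (1, H, W)).astype(np.float32)
        field = StabilizedField(volume=vol, times=times,
                                valid=np.ones((H, W), bool), reference_index=0,
                                fps=7.0, source_indices=np.arange(T))
        with pytest.warns(UserWarning, match="fewer distinct profiles"):
            cluster_field(field, k=2, seed=0, feature_mode="milestones")


class TestRender:
    def test_all_invalid_is_grey(self):
        img = render(np.full((5, 5), np.nan), kind="sequential")
        assert np.all(img == 128)

    def test_zero_slope_map_uniform_midpoint(self):
        img = render(np.zeros((6, 6)), kind="diverging")
        center = img[0, 0]
        assert np.all(img == center)
        assert abs(int(center[0]) - int(center[2])) < 30  # near-neutral hue

    def test_extremes_hit_palette_endpoints(self):
        m = np.array([[0.0, 50.0], [100.0, 25.0]])
        img = render(m, kind="sequential")
        from matplotlib import colormaps

        lo = (np.array(colormaps["viridis"](0.0)[:3]) * 255).astype(int)
        hi = (np.array(colormaps["viridis"](1.0)[:3]) * 255).astype(int)
        assert np.abs(img[0, 0].astype(int) - lo).max() <= 1
        assert np.abs(img[1, 0].astype(int) - hi).max() <= 1
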