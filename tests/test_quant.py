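"""Ingress, ingress rate, zone quantification and per-pixel perfusion maps."""

import numpy as np
import pytest

import flapflow as ff
from flapflow.errors import GeometryError, ParameterError
from flapflow.synthetic import preset_kinetics

from conftest import random_curve


def curve_from(values, rate=4.0):
    values = np.asarray(values, dtype=float)
    return ff.PerfusionCurve(times=np.arange(values.size) / rate, values=values)


class TestCurveExtraction:
    def test_single_pixel_mask_returns_pixel_course(self, noiseless, geometry):
        stack, _ = noiseless[1]
        mask = np.zeros(geometry.shape, dtype=bool)
        r, c = geometry.perforator
        mask[r, c] = True
        curve = ff.roi_mean_curve(stack, mask)
        np.testing.assert_array_equal(curve.values, stack.frames[:, r, c])

    def test_constant_stack_gives_constant_curve(self):
        stack = ff.FrameStack(frames=np.full((10, 4, 4), 7.0), frame_rate=4.0)
        curve = ff.roi_mean_curve(stack, np.ones((4, 4), dtype=bool))
        np.testing.assert_allclose(curve.values, 7.0)

    def test_mean_equals_brute_force_summation(self, noiseless, zones):
        """The ROI curve equals a per-frame double loop over in-mask pixels."""
        stack, _ = noiseless[2]
        mask = zones.roi2
        curve = ff.roi_mean_curve(stack, mask)
        idx = np.argwhere(mask)[::7]  # subsample pixels for the slow oracle
        sub = np.zeros(stack.n_frames)
        for r, c in idx:
            sub += stack.frames[:, r, c]
        # oracle on the full mask for a handful of frames
        for t in (0, 20, 40, 79):
            total = sum(stack.frames[t, r, c] for r, c in np.argwhere(mask))
            assert curve.values[t] == pytest.approx(total / mask.sum(), rel=1e-6)

    def test_empty_mask_rejected(self, noiseless, geometry):
        stack, _ = noiseless[1]
        with pytest.raises(GeometryError):
            ff.roi_mean_curve(stack, np.zeros(geometry.shape, dtype=bool))


class TestBaselineAndIngress:
    def test_baseline_examples(self):
        curve = curve_from([10, 10, 10, 50, 90])
        assert ff.estimate_baseline(curve, window=3) == 10.0
        assert ff.estimate_baseline(curve, window=1) == 10.0
        with pytest.raises(ParameterError):
            ff.estimate_baseline(curve, window=9)

    def test_constant_curve_has_zero_ingress_and_rate(self):
        params = ff.perfusion_params(curve_from(np.full(40, 12.0)))
        assert params.ingress == 0.0
        assert params.ingress_rate == 0.0

    def test_linear_ramp_ingress(self):
        vals = np.linspace(10, 50, 81)
        params = ff.compute_ingress(curve_from(vals), window=1)
        assert params.ingress == pytest.approx(40.0)
        assert params.t_peak == pytest.approx(20.0)

    def test_linear_ramp_rate(self):
        """0 -> 40 APU over 20 s with onset at t = 0 gives 2 APU/s."""
        vals = np.linspace(0, 40, 81)
        rate = ff.compute_ingress_rate(curve_from(vals), window=1)
        assert rate == pytest.approx(2.0, rel=1e-6)

    def test_noiseless_gamma_rate_matches_dense_grid_oracle(self):
        """Rate on a sampled noiseless bolus curve agrees with an oracle that
        finds onset and peak on a dense grid of the continuous curve."""
        b, a, t0, tp, alpha, rate_hz = 10.0, 100.0, 2.0, 5.0, 2.0, 4.0
        times = np.arange(80) / rate_hz
        curve = curve_from(ff.gamma_variate(times, b, a, t0, tp, alpha), rate=rate_hz)
        measured = ff.compute_ingress_rate(curve, window=4)
        # dense-grid oracle: onset = first t with f > B, peak = argmax
        tt = np.linspace(0, 20, 200001)
        fv = ff.gamma_variate(tt, b, a, t0, tp, alpha)
        t_onset = tt[np.flatnonzero(fv > b)[0]]
        t_peak = tt[np.argmax(fv)]
        oracle = (fv.max() - b) / (t_peak - t_onset)
        assert measured == pytest.approx(oracle, rel=0.02)

    def test_ingress_floored_at_zero(self):
        vals = np.concatenate([np.full(4, 50.0), np.linspace(50, 10, 40)])
        params = ff.compute_ingress(curve_from(vals))
        assert params.ingress == 0.0

    @pytest.mark.parametrize("scale,offset", [(2.0, 0.0), (0.5, 10.0), (7.0, 3.0)])
    def test_affine_equivariance(self, scale, offset):
        """a*F + b scales ingress and rate by a; onset/peak times unchanged."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            curve = random_curve(rng)
            p0 = ff.perfusion_params(curve)
            p1 = ff.perfusion_params(
                ff.PerfusionCurve(times=curve.times, values=scale * curve.values + offset)
            )
            assert p1.ingress == pytest.approx(scale * p0.ingress, rel=1e-9)
            assert p1.ingress_rate == pytest.approx(scale * p0.ingress_rate, rel=1e-9)
            assert p1.t_onset == p0.t_onset
            assert p1.t_peak == p0.t_peak

    def test_max_slope_method_on_ramp(self):
        vals = np.linspace(0, 40, 81)
        rate = ff.compute_ingress_rate(curve_from(vals), window=1, rate_method="max_slope")
        assert rate == pytest.approx(2.0, rel=1e-6)


class TestZoneQuantification:
    def test_focal_pattern_has_dominant_roi2(self, noiseless, geometry):
        stack, _ = noiseless[2]
        zp = ff.quantify_zones(stack, geometry)
        others = [zp.rois[k].ingress for k in ("roi1", "roi3", "roi4")]
        assert zp.rois["roi2"].ingress > max(others)

    def test_zone_ingress_matches_ground_truth(self, noiseless, geometry):
        """Noiseless regional ingress equals the closed-form zone truth."""
        stack, truth = noiseless[1]
        zp = ff.quantify_zones(stack, geometry)
        for name in ("roi1", "roi2", "roi3", "roi4"):
            assert zp.rois[name].ingress == pytest.approx(truth.zone_ingress[name], abs=5e-3)

    def test_uniform_video_all_zones_zero(self, geometry):
        stack = ff.FrameStack(frames=np.full((80, *geometry.shape), 9.0), frame_rate=4.0)
        zp = ff.quantify_zones(stack, geometry)
        assert zp.whole_flap.ingress == 0.0
        assert all(p.ingress == 0.0 for p in zp.rois.values())

    def test_untrimmed_stack_warns(self, geometry):
        stack, _ = ff.simulate_flap_video(geometry, preset=1, noise_sd=0.0, seed=0)
        with pytest.warns(UserWarning, match="standard cut"):
            ff.quantify_zones(stack, geometry)


class TestPerfusionMap:
    def test_noiseless_map_equals_amplitude_field(self, noiseless, geometry):
        stack, truth = noiseless[3]
        pmap = ff.perfusion_map(stack, geometry.mask)
        np.testing.assert_allclose(
            pmap.ingress[geometry.mask], truth.amplitude[geometry.mask], atol=1e-3
        )
        assert (pmap.ingress[~geometry.mask] == 0).all()

    def test_constant_video_gives_zero_map(self, geometry):
        stack = ff.FrameStack(frames=np.full((81, *geometry.shape), 5.0), frame_rate=4.0)
        pmap = ff.perfusion_map(stack, geometry.mask)
        assert (pmap.ingress == 0).all()

    def test_region_mean_of_map_bounds_curve_ingress(self, geometry, zones):
        """Max of the mean curve is at most the mean of per-pixel maxima;
        equality holds when all pixels peak simultaneously (instant spread)."""
        kin = preset_kinetics(1)
        # finite speed: desynchronized peaks, strict inequality
        stack, _ = ff.simulate_flap_video(geometry, preset=1, noise_sd=0.0, seed=0)
        stack = ff.trim_to_duration(stack)
        pmap = ff.perfusion_map(stack, geometry.mask)
        curve_ing = ff.compute_ingress(ff.roi_mean_curve(stack, zones.roi2)).ingress
        map_mean = pmap.ingress[zones.roi2].mean()
        assert curve_ing <= map_mean + 1e-6
        # near-infinite speed: synchronized peaks, equality
        from dataclasses import replace

        fast = replace(kin, speed_mm_s=1e9)
        stack2, _ = ff.simulate_flap_video(
            geometry, preset=1, kinetics=fast, noise_sd=0.0, seed=0
        )
        stack2 = ff.trim_to_duration(stack2)
        pmap2 = ff.perfusion_map(stack2, geometry.mask)
        curve_ing2 = ff.compute_ingress(ff.roi_mean_curve(stack2, zones.roi2)).ingress
        assert curve_ing2 == pytest.approx(pmap2.ingress[zones.roi2].mean(), rel=1e-4)

    def test_render_writes_png(self, tmp_path, noiseless, geometry):
        stack, _ = noiseless[1]
        pmap = ff.perfusion_map(stack, geometry.mask)
        out = tmp_path / "map.png"
        ff.render_map(pmap, out)
        assert out.exists() and out.stat().st_size > 0
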