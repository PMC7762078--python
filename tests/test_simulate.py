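"""Forward-model unit tests: optics laws, kinetics, rendering, determinism."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from braggsense import (
    BindingParams,
    ConfigError,
    OpticsParams,
    binding_response,
    build_height_map,
    diffraction_efficiency,
    render_fluorescence,
    simulate_timelapse,
)
from conftest import make_config, replace


class TestDiffractionEfficiency:
    @pytest.mark.parametrize(
        "h, w, c, expected",
        [
            (0.0, 300.0, 1.0, 0.0),  # zero height diffracts nothing
            (30.0, 300.0, 1.0, 30.0),  # at the height ceiling
            (60.0, 300.0, 1.0, 30.0),  # saturated above w/10
            (15.0, 300.0, 2.0, 30.0),  # linear below saturation
        ],
    )
    def test_piecewise_linear_law(self, h, w, c, expected):
        assert diffraction_efficiency(h, w, c) == pytest.approx(expected)

    def test_vectorized_and_monotone(self):
        h = np.linspace(0, 90, 200)
        d = diffraction_efficiency(h, 300.0, 1.5)
        assert np.all(np.diff(d) >= 0)
        below = h <= 30
        assert np.allclose(d[below], 1.5 * h[below])
        assert np.allclose(d[~below], 1.5 * 30.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(height_nm=-1.0, line_width_nm=300.0, diffraction_per_nm=1.0),
            dict(height_nm=np.nan, line_width_nm=300.0, diffraction_per_nm=1.0),
            dict(height_nm=10.0, line_width_nm=0.0, diffraction_per_nm=1.0),
            dict(height_nm=10.0, line_width_nm=300.0, diffraction_per_nm=-0.5),
        ],
    )
    def test_rejects_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            diffraction_efficiency(**kwargs)


class TestBindingResponse:
    def test_zero_before_addition(self):
        p = BindingParams(amplitude=0.3, rate_per_min=1.0, height_scaling=False)
        assert binding_response(2.0, 5.0, p) == 0.0
        assert binding_response(5.0, 5.0, p) == 0.0

    def test_characteristic_time_and_saturation(self):
        p = BindingParams(amplitude=0.3, rate_per_min=0.5, height_scaling=False)
        t0 = 5.0
        at_tau = binding_response(t0 + 1 / 0.5, t0, p)
        assert at_tau == pytest.approx(0.3 * (1 - np.exp(-1)), rel=1e-12)
        assert binding_response(t0 + 1e4, t0, p) == pytest.approx(0.3, rel=1e-9)

    def test_height_scaling_caps_at_one(self):
        p = BindingParams(amplitude=0.2, rate_per_min=10.0, height_scaling=True)
        late = 1e4
        half = binding_response(late, 0.1, p, height_nm=15.0, max_height_nm=30.0)
        full = binding_response(late, 0.1, p, height_nm=30.0, max_height_nm=30.0)
        over = binding_response(late, 0.1, p, height_nm=90.0, max_height_nm=30.0)
        assert half == pytest.approx(0.1, rel=1e-6)
        assert full == pytest.approx(0.2, rel=1e-6)
        assert over == pytest.approx(0.2, rel=1e-6)

    def test_monotone_nondecreasing_in_time(self):
        p = BindingParams(amplitude=0.25, rate_per_min=0.7, height_scaling=False)
        t = np.linspace(0, 30, 400)
        r = binding_response(t, 5.0, p)
        assert np.all(np.diff(r) >= 0)


class TestFluorescence:
    def test_affine_in_height_without_noise(self, rng):
        cfg = make_config(sigma_log=0.3, median_nm=20.0)
        hm = build_height_map(cfg, rng)
        img = render_fluorescence(hm, cfg.optics)
        expected = cfg.optics.fluorescence_per_nm * hm.h + cfg.optics.background_level
        np.testing.assert_allclose(img, expected)
        # doubling height doubles the background-subtracted signal
        h1, h2 = hm.h.copy(), 2 * hm.h
        hm2 = replace(hm, h=h2)
        img2 = render_fluorescence(hm2, cfg.optics)
        np.testing.assert_allclose(img2 - cfg.optics.background_level,
                                   2 * (img - cfg.optics.background_level))

    def test_perfect_height_correlation_without_noise(self, rng):
        cfg = make_config(sigma_log=0.3, median_nm=20.0)
        hm = build_height_map(cfg, rng)
        img = render_fluorescence(hm, cfg.optics)
        r = pearsonr(img[hm.bragg_truth], hm.h[hm.bragg_truth]).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_uniform_background_when_no_gratings(self, rng):
        cfg = make_config(scatter_fraction=0.0)
        cfg.spots = []
        hm = build_height_map(cfg, rng)
        img = render_fluorescence(hm, cfg.optics)
        assert np.all(img == cfg.optics.background_level)


class TestFrameRendering:
    def test_noise_free_frame_composition(self):
        cfg = make_config(noise_sd=0.0, sigma_log=0.3, median_nm=20.0)
        stack, fluor, gt = simulate_timelapse(cfg)
        opt = cfg.optics
        bragg = gt.height_map.bragg_truth
        t_late = stack.times_min[-1]
        resp = 0.2 * np.minimum(gt.height_map.h[bragg] / 30.0, 1.0) * \
            -np.expm1(-0.6 * (t_late - cfg.analyte_time_min))
        d = diffraction_efficiency(gt.height_map.h[bragg], cfg.line_width_nm, opt.diffraction_per_nm)
        frame = stack.frames[-1]
        np.testing.assert_allclose(frame[..., 1][bragg] - opt.background_level, d * (1 + resp))
        np.testing.assert_allclose(
            frame[..., 0][bragg] - opt.background_level,
            d * (1 + resp) / opt.bragg_green_red_contrast,
        )
        np.testing.assert_allclose(frame[..., 0][bragg], frame[..., 2][bragg])

    def test_scatter_pixels_are_color_neutral(self):
        cfg = make_config(noise_sd=0.0)
        stack, _, gt = simulate_timelapse(cfg)
        sm = gt.scatter_mask
        assert sm.any()
        frame = stack.frames[0]
        np.testing.assert_array_equal(frame[..., 0][sm], frame[..., 1][sm])
        np.testing.assert_array_equal(frame[..., 1][sm], frame[..., 2][sm])
        lo, hi = cfg.optics.scatter_level_range
        assert np.all((frame[..., 1][sm] >= lo) & (frame[..., 1][sm] <= hi))

    def test_control_spot_frames_constant_over_time(self):
        cfg = make_config(amplitude=0.0, noise_sd=0.0)
        stack, _, _ = simulate_timelapse(cfg)
        np.testing.assert_array_equal(stack.frames[0], stack.frames[-1])

    def test_control_statistics_stationary_under_noise(self):
        cfg = make_config(amplitude=0.0, noise_sd=0.005, seed=7)
        stack, _, gt = simulate_timelapse(cfg)
        spot = gt.height_map.bragg_truth
        first = stack.frames[0, :, :, 1][spot].mean()
        last = stack.frames[-1, :, :, 1][spot].mean()
        tol = 5 * cfg.noise_sd / np.sqrt(spot.sum())
        assert abs(first - last) < 2 * tol


class TestTimelapse:
    def test_frame_count_and_timestamps(self):
        cfg = make_config(duration_min=20.0, frame_rate_per_min=5.0)
        stack, _, _ = simulate_timelapse(cfg)
        assert stack.n_frames == 101
        assert stack.times_min[0] == 0.0
        assert stack.times_min[1] == pytest.approx(0.2)
        assert stack.times_min[-1] == pytest.approx(20.0)

    def test_seeded_determinism_bit_identical(self):
        cfg1 = make_config(noise_sd=0.005, defect_fraction=0.1, defect_noise_sd=0.05, seed=3)
        cfg2 = make_config(noise_sd=0.005, defect_fraction=0.1, defect_noise_sd=0.05, seed=3)
        s1, f1, _ = simulate_timelapse(cfg1)
        s2, f2, _ = simulate_timelapse(cfg2)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(f1, f2)
        cfg3 = make_config(noise_sd=0.005, defect_fraction=0.1, defect_noise_sd=0.05, seed=4)
        s3, _, _ = simulate_timelapse(cfg3)
        assert not np.array_equal(s1.frames, s3.frames)

    def test_no_spots_gives_background_and_scatter_only(self):
        cfg = make_config(noise_sd=0.0)
        cfg.spots = []
        stack, _, gt = simulate_timelapse(cfg)
        frame = stack.frames[0]
        plain = ~gt.scatter_mask
        assert np.all(frame[plain] == cfg.optics.background_level)

    def test_ground_truth_invariants(self):
        cfg = make_config(noise_sd=0.005, defect_fraction=0.1)
        _, _, gt = simulate_timelapse(cfg)
        hm = gt.height_map
        assert np.array_equal(hm.bragg_truth, hm.h > 0)
        assert np.all(hm.h[hm.spot_label == -1] == 0)
        assert not np.any(gt.scatter_mask & hm.bragg_truth)
        assert np.all(hm.bragg_truth[gt.defect_mask])

    def test_invalid_config_lists_offending_fields(self):
        cfg = make_config()
        cfg.analyte_time_min = 30.0  # after the end of the run
        cfg.scatter_fraction = 1.5
        with pytest.raises(ConfigError) as err:
            simulate_timelapse(cfg)
        assert "analyte_time_min" in str(err.value)
        assert "scatter_fraction" in str(err.value)

    def test_control_with_nonzero_amplitude_rejected(self):
        cfg = make_config(amplitude=0.2)
        cfg.spots = [replace(cfg.spots[0], functionalized=False)]
        with pytest.raises(ConfigError):
            simulate_timelapse(cfg)
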