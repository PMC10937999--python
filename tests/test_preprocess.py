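"""Five-step pretreatment: clipping, filling, denoising, baseline, norm."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from sklearn.base import clone

from ftir_radsig.io import HyperspectralMap
from ftir_radsig.preprocess import (BandMaxNormalizer, PreprocessParams,
                                    RubberbandBaseline, clip_range,
                                    fill_dead_pixels, median_denoise,
                                    normalize_amide2, preprocess_map,
                                    rubberband_baseline)
from ftir_radsig.synth import SyntheticConfig, generate_map


def constant_map(value=0.5, shape=(6, 6), npts=64):
    axis = np.linspace(3590, 910, npts)
    return HyperspectralMap(np.full(shape + (npts,), value), axis)


class TestClipRange:
    def test_output_within_clip_window(self, small_config):
        m = generate_map(small_config, 0.0, 14, seed=1)
        c = clip_range(m)
        assert c.axis.max() <= 3600 and c.axis.min() >= 900
        assert c.absorbance.shape[2] == c.axis.size

    def test_idempotent(self, small_config):
        m = generate_map(small_config, 0.0, 14, seed=1)
        once = clip_range(m)
        twice = clip_range(once)
        np.testing.assert_array_equal(once.absorbance, twice.absorbance)

    def test_full_range_clip_is_identity(self):
        m = constant_map()
        c = clip_range(m, PreprocessParams(clip_window=(900, 3600)))
        np.testing.assert_array_equal(c.absorbance, m.absorbance)


class TestFillDeadPixels:
    def test_dead_pixel_amid_constant_neighbors_restored_exactly(self):
        m = constant_map()
        m.absorbance[3, 3] = 0.0
        filled, dead = fill_dead_pixels(m)
        assert dead.accepted[3, 3] and dead.n_accepted == 1
        np.testing.assert_allclose(filled.absorbance[3, 3], 0.5)

    def test_no_dead_pixels_is_identity(self):
        m = constant_map()
        filled, dead = fill_dead_pixels(m)
        assert dead.n_accepted == 0
        np.testing.assert_array_equal(filled.absorbance, m.absorbance)

    def test_corner_dead_pixel_uses_inbounds_live_mean(self, rng):
        axis = np.linspace(3590, 910, 16)
        cube = rng.uniform(0.4, 0.6, size=(7, 7, 16))
        cube[0, 0] = 0.0
        m = HyperspectralMap(cube.copy(), axis)
        filled, dead = fill_dead_pixels(m)
        assert dead.accepted[0, 0]
        # brute-force oracle: mean over the in-bounds live 5x5 corner window
        window = cube[0:3, 0:3].reshape(-1, 16)
        live = window.sum(axis=1) > 0.1 * np.median(cube.sum(axis=-1))
        np.testing.assert_allclose(filled.absorbance[0, 0],
                                   window[live].mean(axis=0))

    def test_all_dead_is_error(self):
        m = constant_map(value=0.0)
        with pytest.raises(ValueError, match="unusable"):
            fill_dead_pixels(m)


class TestMedianDenoise:
    def test_constant_map_unchanged(self):
        m = constant_map()
        np.testing.assert_allclose(median_denoise(m).absorbance, 0.5)

    def test_single_pixel_spike_removed(self):
        m = constant_map()
        m.absorbance[2, 2] += 10.0
        out = median_denoise(m)
        np.testing.assert_allclose(out.absorbance, 0.5)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_bruteforce_truncated_median(self, trial):
        rng = np.random.default_rng(100 + trial)
        npts = 6
        cube = rng.normal(size=(7, 7, npts))
        m = HyperspectralMap(cube, np.linspace(2000, 1000, npts))
        fast = median_denoise(m).absorbance
        for r in range(7):
            for c in range(7):
                r0, r1 = max(0, r - 2), min(7, r + 3)
                c0, c1 = max(0, c - 2), min(7, c + 3)
                expect = np.median(cube[r0:r1, c0:c1].reshape(-1, npts), axis=0)
                np.testing.assert_allclose(fast[r, c], expect)


class TestRubberband:
    AXIS = np.linspace(3600, 900, 1500)

    def test_straight_line_annihilated(self):
        line = 0.2 + 3e-5 * self.AXIS
        _, corrected = rubberband_baseline(line, self.AXIS)
        assert np.abs(corrected).max() < 1e-9

    def test_gaussian_peak_height_recovered_within_1pct(self):
        line = 0.1 + 5e-5 * self.AXIS
        peak = 0.8 * np.exp(-0.5 * ((self.AXIS - 1648) / 8.0) ** 2)
        _, corrected = rubberband_baseline(line + peak, self.AXIS)
        i = np.argmin(np.abs(self.AXIS - 1648))
        assert corrected[i] == pytest.approx(0.8, rel=0.01)

    def test_corrected_nonnegative_on_anchor_span(self, rng):
        spec = (0.3 + 4e-5 * self.AXIS
                + np.abs(rng.normal(0, 0.02, self.AXIS.size)))
        _, corrected = rubberband_baseline(spec, self.AXIS)
        inside = (self.AXIS >= 900) & (self.AXIS <= 3600)
        assert corrected[inside].min() >= -1e-9

    def test_matches_scipy_convex_hull_between_two_anchors(self, rng):
        """Independent oracle: qhull lower hull of the (x, y) point cloud."""
        x = np.linspace(900, 1800, 400)
        y = (0.2 + 1e-4 * x
             + 0.5 * np.exp(-0.5 * ((x - 1400) / 60.0) ** 2)
             + 0.2 * np.exp(-0.5 * ((x - 1200) / 30.0) ** 2))
        params = PreprocessParams(clip_window=(900, 1800),
                                  baseline_anchors=(900.0, 1800.0),
                                  anchor_halfwidth=5.0)
        base, _ = rubberband_baseline(y[::-1], x[::-1].copy(), params)
        base = base[::-1]
        hull = ConvexHull(np.column_stack([x, y]))
        verts = np.sort(hull.vertices)
        # lower hull: vertices whose y sits at/below the interpolated chain
        pts = sorted((x[v], y[v]) for v in hull.vertices)
        hx, hy = zip(*pts)
        lower = []
        for px, py in pts:
            while len(lower) >= 2:
                (x1, y1), (x2, y2) = lower[-2], lower[-1]
                if (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1) <= 0:
                    lower.pop()
                else:
                    break
            lower.append((px, py))
        lx, ly = np.array([p[0] for p in lower]), np.array([p[1] for p in lower])
        expect = np.interp(x, lx, ly)
        np.testing.assert_allclose(base, expect, atol=1e-10)

    def test_anchor_outside_axis_is_error(self):
        params = PreprocessParams(clip_window=(900, 3600),
                                  baseline_anchors=(900.0, 3600.0))
        with pytest.raises(ValueError, match="anchor"):
            rubberband_baseline(np.ones(100), np.linspace(2000, 1500, 100),
                                params)


class TestNormalizeAmide2:
    AXIS = np.linspace(3600, 900, 1000)

    def test_window_max_becomes_one(self, rng):
        spec = np.abs(rng.normal(0.3, 0.1, self.AXIS.size)) + 0.01
        out = normalize_amide2(spec, self.AXIS)
        sel = (self.AXIS >= 1480) & (self.AXIS <= 1590)
        assert out[sel].max() == pytest.approx(1.0)

    def test_already_normalized_is_identity(self, rng):
        spec = np.abs(rng.normal(0.3, 0.1, self.AXIS.size)) + 0.01
        once = normalize_amide2(spec, self.AXIS)
        np.testing.assert_allclose(normalize_amide2(once, self.AXIS), once)

    def test_division_by_window_max(self):
        spec = np.zeros_like(self.AXIS)
        spec[np.argmin(np.abs(self.AXIS - 1553))] = 0.5
        spec[np.argmin(np.abs(self.AXIS - 1648))] = 0.9
        out = normalize_amide2(spec, self.AXIS)
        assert out[np.argmin(np.abs(self.AXIS - 1648))] == pytest.approx(1.8)

    def test_nonpositive_window_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_amide2(np.zeros_like(self.AXIS), self.AXIS)


class TestPreprocessMap:
    def test_noise_free_linear_baseline_pipeline(self):
        cfg = SyntheticConfig(
            n_mice_per_group=1, map_shape=(6, 6), n_points=1024,
            noise_sd=0.0, het_noise_coef=0.0,
            baseline_params={"offset": 0.05, "slope": 0.03},
            dead_pixel_rate=0.0, co2_amplitude=0.0, pixel_scale_sd=0.0,
            baseline_pixel_sd=0.0, seed=2,
        )
        m = generate_map(cfg, 0.0, 14, seed=2)
        out, info = preprocess_map(m, return_info=True)
        assert info["normalized_ok"].all()
        sel = (out.axis >= 1480) & (out.axis <= 1590)
        np.testing.assert_allclose(out.absorbance[..., sel].max(axis=-1), 1.0)
        # far from bands the baseline-corrected signal is near zero
        quiet = (out.axis >= 1900) & (out.axis <= 2200)
        assert np.abs(out.absorbance[..., quiet]).max() < 0.01

    def test_approximately_idempotent_on_noise_free_map(self):
        # after the first normalization, noise-free pixels coincide, so the
        # spatial filters and the hull become identities on the second pass
        cfg = SyntheticConfig(
            n_mice_per_group=1, map_shape=(6, 6), n_points=1024,
            noise_sd=0.0, het_noise_coef=0.0,
            baseline_params={"offset": 0.05, "slope": 0.03},
            dead_pixel_rate=0.0, co2_amplitude=0.0, pixel_scale_sd=0.05,
            baseline_pixel_sd=0.0, seed=2,
        )
        m = generate_map(cfg, 0.0, 14, seed=4)
        once = preprocess_map(m)
        twice = preprocess_map(once)
        denom = np.abs(once.absorbance).max()
        assert np.abs(twice.absorbance - once.absorbance).max() / denom < 1e-6

    def test_output_axis_within_clip_window(self, small_config):
        m = generate_map(small_config, 0.0, 14, seed=4)
        out = preprocess_map(m)
        assert out.axis.max() <= 3600 and out.axis.min() >= 900


class TestTransformers:
    AXIS = np.linspace(3600, 900, 800)

    def test_sklearn_pipeline_composition(self, rng):
        from sklearn.pipeline import make_pipeline

        X = (0.2 + 1e-4 * self.AXIS
             + np.abs(rng.normal(0.2, 0.05, size=(5, self.AXIS.size))))
        pipe = make_pipeline(RubberbandBaseline(axis=self.AXIS),
                             BandMaxNormalizer(axis=self.AXIS))
        out = pipe.fit_transform(X)
        sel = (self.AXIS >= 1480) & (self.AXIS <= 1590)
        np.testing.assert_allclose(out[:, sel].max(axis=1), 1.0)

    def test_clone_preserves_params(self):
        t = RubberbandBaseline(axis=self.AXIS, anchor_halfwidth=30.0)
        assert clone(t).anchor_halfwidth == 30.0
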