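"""Intensity conditioning and tuning-score behavior."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from useg3d import preprocess as pp

from conftest import brute_local_sd


class TestNormalizePercentile:
    def test_full_range_ramp(self):
        ramp = np.linspace(0, 100, 11 * 11 * 11).reshape(11, 11, 11)
        out = pp.normalize_percentile(ramp, pp.NormalizeParams(0, 100))
        assert np.allclose(out.min(), 0) and np.allclose(out.max(), 1)
        assert np.all(np.diff(out.ravel()) >= 0)

    def test_default_percentiles_pin_0_and_1(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 20, 20)) * 50
        out = pp.normalize_percentile(img)
        lo, hi = np.percentile(img, [2.0, 99.8])
        mapped = np.clip((np.array([lo, hi]) - lo) / (hi - lo), 0, 1)
        assert np.allclose(mapped, [0.0, 1.0])
        assert out.min() >= 0 and out.max() <= 1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            pp.normalize_percentile(np.ones((5, 5, 5)))

    def test_idempotent_with_full_range(self):
        rng = np.random.default_rng(1)
        img = rng.random((8, 8, 8))
        once = pp.normalize_percentile(img, pp.NormalizeParams(0, 100))
        twice = pp.normalize_percentile(once, pp.NormalizeParams(0, 100))
        assert np.allclose(once, twice)


class TestIllumination:
    def test_constant_image_fixed_point(self):
        img = np.full((16, 16, 16), 7.0)
        out = pp.correct_illumination(img, sigma_bg=3.0, ds=2)
        assert np.allclose(out, 7.0, rtol=1e-4)

    def test_shading_background_flattened(self):
        z, y, x = np.meshgrid(*[np.linspace(0, 1, 32)] * 3, indexing="ij")
        shade = 0.5 + 0.5 * x  # smooth multiplicative shading
        rng = np.random.default_rng(2)
        img = shade * (1.0 + 0.01 * rng.random((32, 32, 32)))
        out = pp.correct_illumination(img, sigma_bg=4.0, ds=2)
        cv_in = img.std() / img.mean()
        cv_out = out.std() / out.mean()
        assert cv_out < cv_in

    def test_ds1_equals_direct_gaussian_division(self):
        rng = np.random.default_rng(3)
        img = rng.random((12, 12, 12)) + 0.5
        out = pp.correct_illumination(img, sigma_bg=2.0, ds=1)
        bg = ndi.gaussian_filter(img, 2.0)
        assert np.allclose(out, img.mean() * img / (bg + 1e-8 * max(bg.max(), 1.0)))


class TestGamma:
    def test_identity_after_rescale(self):
        rng = np.random.default_rng(4)
        img = rng.random((6, 6, 6)) * 9 + 1
        out = pp.gamma_correct(img, 1.0)
        assert np.allclose(out, (img - img.min()) / (img.max() - img.min()))

    def test_known_value(self):
        img = np.zeros((4, 4, 4))
        img[0, 0, 0] = 1.0
        img[1, 1, 1] = 0.25
        out = pp.gamma_correct(img, 0.5)
        assert np.isclose(out[1, 1, 1], 0.5)

    def test_monotone(self):
        rng = np.random.default_rng(5)
        img = rng.random((5, 5, 5))
        out = pp.gamma_correct(img, 0.4)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= -1e-12)


class TestRidges:
    def test_zero_image_zero_response(self):
        assert np.allclose(pp.enhance_ridges(np.zeros((16, 16, 16))), 0)

    def test_tube_beats_blob(self):
        img_tube = np.zeros((40, 40))
        img_tube[19:21, 5:35] = 1.0
        img_blob = np.zeros((40, 40))
        yy, xx = np.ogrid[:40, :40]
        img_blob[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = 1.0
        rt = pp.enhance_ridges(ndi.gaussian_filter(img_tube, 1), sigmas=[1, 2])
        rb = pp.enhance_ridges(ndi.gaussian_filter(img_blob, 1), sigmas=[1, 2])
        assert rt[20, 20] > rb[20, 20]

    def test_offset_invariance(self):
        rng = np.random.default_rng(6)
        img = ndi.gaussian_filter(rng.random((24, 24)), 2)
        a = pp.enhance_ridges(img, sigmas=[1.5])
        b = pp.enhance_ridges(img + 10.0, sigmas=[1.5])
        assert np.allclose(a, b, atol=1e-8)


class TestProbability:
    def test_logistic_fixed_points(self):
        assert pp.normalize_probability(0.0) == 0.5
        assert np.isclose(pp.normalize_probability(1000.0), 1.0 / (1.0 + np.exp(-88.72)))
        x = np.linspace(-5, 5, 101)
        assert np.all(np.diff(pp.normalize_probability(x)) > 0)

    def test_otsu_threshold_between_modes(self):
        rng = np.random.default_rng(7)
        p = np.concatenate(
            [
                np.clip(rng.normal(0.1, 0.03, 4000), 0, 1),
                np.clip(rng.normal(0.9, 0.03, 4000), 0, 1),
            ]
        )
        t = pp.auto_threshold_probability(p)
        assert 0.15 < t < 0.85
        # exhaustive Otsu oracle over 256 bins: maximize between-class variance
        hist, edges = np.histogram(p, bins=256, range=(0, 1))
        best, best_t = -1.0, 0.0
        for i in range(1, 256):
            w0, w1 = hist[:i].sum(), hist[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            centers = (edges[:-1] + edges[1:]) / 2
            m0 = (hist[:i] * centers[:i]).sum() / w0
            m1 = (hist[i:] * centers[i:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best:
                best, best_t = v, centers[i - 1]
        assert abs(t - best_t) < 0.05

    def test_floor_and_round_down(self):
        rng = np.random.default_rng(8)
        p = np.clip(rng.normal(0.06, 0.02, 5000), 0, 1)
        p[::50] = 0.15
        t = pp.auto_threshold_probability(p, floor=0.25)
        assert t == 0.25
        u = np.linspace(0, 1, 1000) ** 2  # skewed, threshold not on a decimal
        raw = pp.auto_threshold_probability(u)
        rounded = pp.auto_threshold_probability(u, round_down=True)
        assert rounded == np.floor(raw * 10) / 10

    def test_three_class_picks(self):
        rng = np.random.default_rng(9)
        p = np.concatenate(
            [rng.normal(m, 0.02, 3000) for m in (0.1, 0.5, 0.9)]
        ).clip(0, 1)
        lo = pp.auto_threshold_probability(p, classes=3, pick="lower")
        hi = pp.auto_threshold_probability(p, classes=3, pick="higher")
        assert lo < hi


class TestContrastScore:
    def test_uniform_field_scores_zero(self):
        g = np.ones((20, 20))
        assert pp.contrast_score(g, g, P=3, use_p=False) == 0.0

    def test_checkerboard_matches_sliding_window_oracle(self):
        yy, xx = np.indices((16, 16))
        gx = np.where((yy + xx) % 2 == 0, 1.0, -1.0)
        gy = np.zeros_like(gx)
        score = pp.contrast_score(gx, gy, P=3, use_p=False)
        oracle = float(np.mean(brute_local_sd(gx, 3) + brute_local_sd(gy, 3)))
        assert np.isclose(score, oracle, rtol=1e-10)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(10)
        gx, gy = rng.random((2, 15, 15))
        w = rng.random((15, 15))
        s1 = pp.contrast_score(gx, gy, p=w, P=3)
        s2 = pp.contrast_score(gx, gy, p=2 * w, P=3)
        assert np.isclose(s2, 2 * s1)


class TestScanDiameter:
    @staticmethod
    def _predictor_peaked_at(d_star):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((32, 32))

        def predictor(image2d, d):
            amp = np.exp(-((d - d_star) ** 2) / (2 * 15.0**2))
            return amp * noise, amp * noise[::-1], np.zeros((32, 32))

        return predictor

    def test_finds_known_peak(self):
        curve = pp.scan_diameter(
            self._predictor_peaked_at(30.0),
            np.zeros((32, 32)),
            d_low=10,
            d_high=120,
            step=5,
            use_p=False,
        )
        assert curve.d_opt == 30.0

    def test_window_one_is_raw(self):
        curve = pp.scan_diameter(
            self._predictor_peaked_at(50.0),
            np.zeros((32, 32)),
            d_low=10,
            d_high=60,
            step=10,
            window=1,
            use_p=False,
        )
        assert np.array_equal(curve.smoothed, curve.scores)

    def test_predictor_failure_carries_diameter(self):
        def bad(image2d, d):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="diameter 10"):
            pp.scan_diameter(bad, np.zeros((8, 8)), d_low=10, d_high=20, step=5)


class TestReferenceSlice:
    def test_focus_picks_sharp_slice(self):
        rng = np.random.default_rng(11)
        sharp = rng.random((32, 32))
        stack = np.stack([ndi.gaussian_filter(sharp, 3)] * 7)
        stack[4] = sharp
        assert pp.select_reference_slice(stack, "focus") == 4

    def test_mid_and_intensity(self):
        stack = np.zeros((11, 8, 8))
        stack[2] = 5.0
        assert pp.select_reference_slice(stack, "mid") == 5
        assert pp.select_reference_slice(stack, "intensity") == 2

    def test_index_bounds(self):
        with pytest.raises(ValueError):
            pp.select_reference_slice(np.zeros((3, 4, 4)), "index", index=9)
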