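"""Anisotropy, background, calibration and four-channel inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polarmic as pm
from polarmic.polarimetry import SNR_CUTOFF


class TestBackground:
    def test_pure_gaussian_background(self, rng):
        img = rng.normal(100.0, 10.0, size=(256, 256))
        bg = pm.estimate_background(img)
        assert bg.mu == pytest.approx(100.0, rel=0.02)
        assert bg.sigma == pytest.approx(10.0, rel=0.05)
        assert bg.mask_threshold == pytest.approx(bg.mu + 3 * bg.sigma)

    def test_constant_image(self):
        bg = pm.estimate_background(np.full((64, 64), 7.0))
        assert bg.mu == 7.0
        assert bg.sigma == 0.0
        assert bg.mask_threshold == 7.0

    def test_bright_foreground_ignored(self, rng):
        img = rng.normal(100.0, 10.0, size=(256, 256))
        yy, xx = np.mgrid[0:256, 0:256]
        disk = (yy - 128) ** 2 + (xx - 128) ** 2 < 50**2
        contaminated = img.copy()
        contaminated[disk] = 1e4
        bg_clean = pm.estimate_background(img)
        bg = pm.estimate_background(contaminated)
        assert bg.mu == pytest.approx(bg_clean.mu, rel=0.02)
        assert bg.sigma == pytest.approx(bg_clean.sigma, rel=0.02)

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            pm.estimate_background(np.ones((10, 10)))


class TestGFactor:
    def test_identical_channels(self):
        img = np.full((64, 64), 50.0)
        pair = pm.PolarPairStack(I_par=img, I_perp=img)
        assert pm.g_factor_from_isotropic(pair) == pytest.approx(1.0)

    def test_perp_twice_par_gives_half_and_zero_r(self):
        par = np.full((64, 64), 50.0)
        pair = pm.PolarPairStack(I_par=par, I_perp=2 * par)
        g = pm.g_factor_from_isotropic(pair)
        assert g == pytest.approx(0.5)
        corrected = pm.PolarPairStack(I_par=par, I_perp=2 * par, g_factor=g)
        amap = pm.anisotropy(corrected, bg=None, prefilter=False)
        assert np.allclose(amap.r[amap.valid], 0.0)

    def test_round_trip_recovers_scene(self, noiseless_ea_scene):
        pair, gt = noiseless_ea_scene
        g_true = 0.8
        skew = pm.PolarPairStack(I_par=pair.I_par, I_perp=pair.I_perp / g_true,
                                 g_factor=g_true)
        bg = pm.estimate_background(skew.I_perp)
        amap = pm.anisotropy(skew, bg=bg, prefilter=False)
        sel = amap.valid & np.isfinite(gt.anisotropy)
        assert np.allclose(amap.r[sel], gt.anisotropy[sel], atol=1e-9)

    def test_zero_perp_errors(self):
        pair = pm.PolarPairStack(I_par=np.ones((32, 32)), I_perp=np.zeros((32, 32)))
        with pytest.raises(ValueError):
            pm.g_factor_from_isotropic(pair)


class TestAnisotropy:
    @pytest.mark.parametrize("par, perp, expected", [
        (2.0, 2.0, 0.0),     # equal channels
        (1.0, 0.0, 1.0),     # fully parallel
        (0.0, 1.0, -0.5),    # fully perpendicular
        (3.0, 1.0, 0.4),     # (3-1)/(3+2) = 0.4
    ])
    def test_identities(self, par, perp, expected):
        pair = pm.PolarPairStack(I_par=np.full((8, 8), par),
                                 I_perp=np.full((8, 8), perp))
        amap = pm.anisotropy(pair, bg=None, prefilter=False)
        assert np.allclose(amap.r[amap.valid], expected)

    def test_range_invariant_on_random_pairs(self, rng):
        par = rng.uniform(0, 1e4, size=(1000, 1000))
        perp = rng.uniform(0, 1e4, size=(1000, 1000))
        pair = pm.PolarPairStack(I_par=par, I_perp=perp)
        amap = pm.anisotropy(pair, bg=None, prefilter=False)
        r = amap.r[amap.valid]
        assert r.min() >= -0.5 - 1e-12 and r.max() <= 1.0 + 1e-12

    @settings(deadline=None, max_examples=50)
    @given(par=st.floats(0, 1e6), perp=st.floats(0, 1e6))
    def test_range_invariant_property(self, par, perp):
        if par + 2 * perp == 0:
            return
        r = (par - perp) / (par + 2 * perp)
        assert -0.5 <= r <= 1.0

    def test_zero_total_marked_invalid_not_nan(self):
        par = np.zeros((8, 8))
        pair = pm.PolarPairStack(I_par=par, I_perp=par)
        amap = pm.anisotropy(pair, bg=None, prefilter=False)
        assert not amap.valid.any()
        assert np.isfinite(amap.r).all()

    def test_prefilter_is_intensity_weighted_neighborhood_mean(self):
        # uniform r field is unchanged by the weighted smoothing
        pair = pm.PolarPairStack(I_par=np.full((1, 16, 16), 3.0),
                                 I_perp=np.full((1, 16, 16), 1.0))
        amap = pm.anisotropy(pair, bg=None, prefilter=True)
        assert np.allclose(amap.r[amap.valid], 0.4)

    def test_prefilter_weights_follow_intensity(self):
        # bright pixel dominates its 3x3 neighborhood mean
        par = np.ones((1, 9, 9))
        perp = np.ones((1, 9, 9))
        par[0, 4, 4], perp[0, 4, 4] = 300.0, 100.0   # r=0 neighbors, r=0.4 center
        pair = pm.PolarPairStack(I_par=par, I_perp=perp)
        amap = pm.anisotropy(pair, bg=None, prefilter=True)
        w_bright = 500.0
        w_dim = 3.0
        expected = (w_bright * 0.4 + 8 * w_dim * 0.0) / (w_bright + 8 * w_dim)
        assert amap.r[0, 4, 4] == pytest.approx(expected)


class TestRegionSNR:
    def test_boundary_inclusive(self):
        bg = pm.BackgroundModel(mu=0.0, sigma=2.0)
        assert pm.region_snr(np.full(50, 10.0), bg) == pytest.approx(5.0)
        assert pm.region_snr(np.full(50, 9.9), bg) < SNR_CUTOFF

    def test_zero_sigma_is_infinite(self):
        bg = pm.BackgroundModel(mu=0.0, sigma=0.0)
        assert np.isinf(pm.region_snr(np.full(10, 1.0), bg))

    def test_exclusion_count_matches_brute_force(self, rng):
        bg = pm.BackgroundModel(mu=0.0, sigma=3.0)
        regions = [rng.uniform(0, 30, size=20) for _ in range(50)]
        excluded = sum(pm.region_snr(reg, bg) < SNR_CUTOFF for reg in regions)
        brute = sum(reg.mean() / 3.0 < 5.0 for reg in regions)
        assert excluded == brute


class TestQuadPolarization:
    def test_worked_example(self):
        qp = pm.quad_polarization(3, 2, 1, 2)
        assert qp.p == pytest.approx(0.5)
        assert qp.theta_deg == pytest.approx(0.0)

    def test_equal_channels_isotropic(self):
        qp = pm.quad_polarization(2, 2, 2, 2)
        assert qp.p == pytest.approx(0.0)
        assert qp.isotropic
        assert np.isnan(qp.theta_deg)

    def test_exhaustive_forward_round_trip(self):
        p_grid = np.arange(0.1, 0.95, 0.1)
        th_grid = np.arange(0.0, 180.0, 5.0)
        alphas = np.array([0.0, 45.0, 90.0, 135.0])
        for p in p_grid:
            for th in th_grid:
                chans = 2.0 * (1 + p * np.cos(np.radians(2 * (alphas - th))))
                qp = pm.quad_polarization(*chans)
                assert qp.p == pytest.approx(p, abs=1e-12)
                assert float(pm.circ_dist180(qp.theta_deg, th)) < 1e-9

    def test_dyad_symmetry(self):
        alphas = np.array([0.0, 45.0, 90.0, 135.0])
        for th in (10.0, 100.0):
            a = 2.0 * (1 + 0.6 * np.cos(np.radians(2 * (alphas - th))))
            b = 2.0 * (1 + 0.6 * np.cos(np.radians(2 * (alphas - th - 180.0))))
            qa, qb = pm.quad_polarization(*a), pm.quad_polarization(*b)
            assert qa.theta_deg == pytest.approx(qb.theta_deg)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            pm.quad_polarization(0, 0, 0, 0)


class TestQuadCalibrate:
    def test_identity_calibration(self, rng):
        chans = [rng.uniform(1, 2, size=(1, 16, 16)) for _ in range(4)]
        quad = pm.quad_calibrate(chans, (1, 1, 1, 1))
        assert np.allclose(quad.I0, chans[0])

    def test_throughput_restored(self, rng):
        base = rng.uniform(1, 2, size=(1, 16, 16))
        quad = pm.quad_calibrate([2 * base, base, base, base], (2, 1, 1, 1))
        assert np.allclose(quad.I0, base)

    def test_idempotent_under_identity(self, rng):
        chans = [rng.uniform(1, 2, size=(1, 16, 16)) for _ in range(4)]
        once = pm.quad_calibrate(chans, (1, 1, 1, 1))
        twice = pm.quad_calibrate([once.I0, once.I45, once.I90, once.I135],
                                  (1, 1, 1, 1))
        assert np.allclose(once.I0, twice.I0)

    def test_round_trip_with_background(self):
        # isotropic cell center: the 4x4 central ROI removes the per-channel
        # offset, so channel differences match the clean scene exactly
        spec = pm.SceneSpec(image_height=64, image_width=64,
                            background_mean=0.0, noise_model="none")
        quad, gt = pm.make_quad_scene(spec, p_inside=0.0, p_leading_edge=0.8)
        factors = (1.5, 0.8, 1.2, 1.0)
        offsets = (10.0, 7.0, 12.0, 9.0)
        raw = [c * f + b for c, f, b in
               zip((quad.I0, quad.I45, quad.I90, quad.I135), factors, offsets)]
        cal = pm.quad_calibrate(raw, factors, center_roi=(30, 30))
        assert np.allclose(cal.I0 - cal.I90, quad.I0 - quad.I90, atol=1e-9)
        assert np.allclose(cal.I45 - cal.I135, quad.I45 - quad.I135, atol=1e-9)

    def test_missing_calibration_errors(self, rng):
        chans = [rng.uniform(1, 2, size=(8, 8)) for _ in range(4)]
        with pytest.raises(ValueError):
            pm.quad_calibrate(chans, None)


class TestDiagnostic:
    def test_flat_relation(self, rng):
        # r constructed independent of a broad intensity range -> slope ~ 0
        inten = rng.uniform(100, 1000, size=(1, 64, 64))
        r = 0.1 + rng.normal(0, 0.01, size=inten.shape)
        amap = pm.AnisotropyMap(r=r, valid=np.ones_like(r, dtype=bool),
                                total_intensity=inten)
        slope, corr = pm.anisotropy_intensity_diagnostic(amap)
        assert abs(slope) * 900.0 < 0.005   # r drift over the range
        assert abs(corr) < 0.1

    def test_injected_slope_detected(self, rng):
        inten = rng.uniform(100, 1000, size=(1, 64, 64))
        r = 1e-4 * inten + rng.normal(0, 1e-3, size=inten.shape)
        amap = pm.AnisotropyMap(r=r, valid=np.ones_like(r, dtype=bool),
                                total_intensity=inten)
        slope, corr = pm.anisotropy_intensity_diagnostic(amap)
        assert slope == pytest.approx(1e-4, rel=0.1)
        assert corr > 0.9

    def test_empty_mask_errors(self, rng):
        r = rng.normal(size=(1, 32, 32))
        amap = pm.AnisotropyMap(r=r, valid=np.zeros_like(r, dtype=bool),
                                total_intensity=r)
        with pytest.raises(ValueError):
            pm.anisotropy_intensity_diagnostic(amap)
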