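import numpy as np
import pytest
from scipy.stats import norm

from petboot.basis import TemporalBasis
from petboot.glm import (
    coefficient_covariance,
    estimate_qtransform,
    estimate_spectrum,
    fit_glm,
    initial_weights,
    iterate_scales,
    residual_diagnostics,
    wls_alpha,
)
from petboot.study import DynamicImage, FrameSchedule, VoxelGrid

from conftest import make_glm_study


class TestInitialWeights:
    def test_hand_evaluated_example(self):
        # oracle: direct evaluation of the weighting rule plus normalization
        sch = FrameSchedule([1.0, 2.0, 4.0], [1.0, 1.0, 2.0], 0.0)
        w0, phi0 = initial_weights(sch, np.array([2.0, 10.0, 5.0]))
        np.testing.assert_allclose(w0, [0.5, 0.1, 0.4])
        np.testing.assert_allclose(phi0, [0.643267, 1.438390, 0.719195], atol=1e-5)
        assert (phi0**2).sum() == pytest.approx(3.0, abs=1e-12)

    def test_constant_frames_give_unit_phi(self):
        sch = FrameSchedule(np.arange(5) + 0.5, np.ones(5), 0.0)
        _, phi0 = initial_weights(sch, np.full(5, 7.0))
        np.testing.assert_allclose(phi0, 1.0)

    def test_zero_frame_mean_floored(self):
        sch = FrameSchedule(np.arange(3) + 0.5, np.ones(3), 0.0)
        w0, _ = initial_weights(sch, np.array([0.0, 10.0, 5.0]))
        assert np.all(np.isfinite(w0))
        assert w0[0] == pytest.approx(1.0 / 1.0)  # floored at 0.1 * max

    def test_all_zero_means_error(self):
        sch = FrameSchedule(np.arange(3) + 0.5, np.ones(3), 0.0)
        with pytest.raises(ValueError, match="no signal"):
            initial_weights(sch, np.zeros(3))

    def test_decay_factor_enters(self):
        sch = FrameSchedule([1.0, 2.0], [1.0, 1.0], 0.5)
        w0, _ = initial_weights(sch, np.array([1.0, 1.0]))
        assert w0[0] / w0[1] == pytest.approx(np.exp(0.5))


class TestWlsAlpha:
    def test_noiseless_interpolation(self):
        rng = np.random.default_rng(0)
        x = rng.random((10, 3))
        alpha = rng.standard_normal((20, 3))
        z = alpha @ x.T
        a_hat, r = wls_alpha(z, x, np.ones(10))
        np.testing.assert_allclose(a_hat, alpha, atol=1e-10)
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(1)
        z = rng.random((7, 6))
        a_hat, _ = wls_alpha(z, np.ones((6, 1)), np.ones(6))
        np.testing.assert_allclose(a_hat[:, 0], z.mean(axis=1))

    def test_matches_explicit_normal_equations(self):
        # oracle: (X'WX)^{-1} X'W z
        rng = np.random.default_rng(2)
        x = rng.random((20, 5))
        w = 0.5 + rng.random(20)
        z = rng.standard_normal((1, 20))
        a_hat, _ = wls_alpha(z, x, w)
        ref = np.linalg.solve((x * w[:, None]).T @ x, (x * w[:, None]).T @ z[0])
        np.testing.assert_allclose(a_hat[0], ref, rtol=1e-10)

    def test_singular_design_names_columns(self):
        x = np.ones((8, 2))
        with pytest.raises(np.linalg.LinAlgError, match="dependent columns"):
            wls_alpha(np.ones((3, 8)), x, np.ones(8))


class TestIterateScales:
    def test_known_product_structure_recovered(self):
        # oracle: the generating sigma/phi of the simulation
        rng = np.random.default_rng(4)
        n, t = 500, 20
        sigma = 0.5 + rng.random(n)
        raw = np.linspace(0.5, 1.5, t)
        phi = np.sqrt(t * raw / raw.sum())
        r = sigma[:, None] * phi[None, :] * rng.standard_normal((n, t))
        zhat = np.abs(rng.standard_normal((n, t))) + 1.0
        sf = iterate_scales(r, zhat, n_basis=0, l_bins=8)
        # per-frame scale from 500 voxels: sampling CV ~ sqrt(2/500) ~ 6%
        np.testing.assert_allclose(sf.phi, phi, rtol=0.2)
        assert np.sqrt(np.mean((sf.phi / phi - 1.0) ** 2)) <= 0.05
        rel = np.sqrt(np.mean((sf.sigma - sigma) ** 2)) / sigma.mean()
        assert rel <= 0.30  # per-voxel scale from t=20 samples
        # the overall scale convention is pinned by sum(phi^2) = T
        assert np.median(sf.sigma / sigma) == pytest.approx(1.0, abs=0.05)

    def test_homogeneous_residuals(self):
        r = np.full((50, 10), 2.0)
        zhat = np.tile(np.linspace(1, 10, 10), (50, 1))
        sf = iterate_scales(r, zhat, n_basis=0, l_bins=4)
        assert np.ptp(sf.sigma) == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sf.phi, 1.0, atol=1e-8)
        np.testing.assert_allclose(sf.h, 1.0, atol=1e-8)

    def test_normalizations_exact(self):
        rng = np.random.default_rng(5)
        r = rng.standard_normal((200, 15))
        zhat = rng.random((200, 15)) + 0.5
        sf = iterate_scales(r, zhat, n_basis=3, l_bins=10)
        assert (sf.phi**2).sum() == pytest.approx(15.0, abs=1e-8)
        assert (sf.h**2).sum() == pytest.approx(10.0, abs=1e-8)

    def test_bias_inflation_applied(self):
        rng = np.random.default_rng(6)
        r = rng.standard_normal((300, 12))
        zhat = np.ones((300, 12))
        sf0 = iterate_scales(r, zhat, n_basis=0, l_bins=4)
        sf4 = iterate_scales(r, zhat, n_basis=4, l_bins=4)
        ratio = sf4.sigma[sf0.sigma > 0] / sf0.sigma[sf0.sigma > 0]
        np.testing.assert_allclose(ratio, np.sqrt(12.0 / 8.0), rtol=1e-8)


class TestQTransform:
    def test_identity_on_normal_quantiles(self):
        n = 400
        eps = norm.ppf((np.arange(1, n + 1) - 0.5) / n).reshape(40, 10)
        q = estimate_qtransform(
            eps, np.ones(40), np.ones(10), np.zeros((40, 10), dtype=int), np.array([])
        )
        np.testing.assert_allclose(q.eta_tables[0], q.eps_tables[0], atol=1e-12)
        assert q.h[0] == pytest.approx(1.0)

    def test_lognormal_bin_is_convex_increasing(self):
        # oracle: transform of the generating lognormal quantiles
        n = 1000
        base = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        vals = np.exp(base)
        vals = (vals - vals.mean()) / vals.std()
        q = estimate_qtransform(
            vals.reshape(100, 10),
            np.ones(100),
            np.ones(10),
            np.zeros((100, 10), dtype=int),
            np.array([]),
        )
        table = q.eps_tables[0]
        assert np.all(np.diff(table) >= 0)
        # convexity: increments grow in the upper tail (positive skewness)
        from scipy.stats import skew

        assert skew(q.transform(np.random.default_rng(0).standard_normal(5000), np.zeros(5000, dtype=int))) > 0.5

    def test_tables_monotone_by_construction(self):
        rng = np.random.default_rng(7)
        eps = rng.standard_normal((60, 10)) * 2 + rng.random((60, 10))
        bins = rng.integers(0, 4, size=(60, 10))
        edges = np.array([-0.5, 0.0, 0.5])
        q = estimate_qtransform(eps, np.ones(60), np.ones(10), bins, edges)
        for tab in q.eps_tables:
            assert np.all(np.diff(tab) >= 0)

    def test_transform_inverse_consistency(self):
        rng = np.random.default_rng(8)
        eps = rng.standard_normal((80, 10))
        bins = np.zeros((80, 10), dtype=int)
        q = estimate_qtransform(eps, np.ones(80), np.ones(10), bins, np.array([]))
        eta = rng.standard_normal(200) * 0.5  # interior of the table
        back = q.inverse(q.transform(eta, np.zeros(200, dtype=int)), np.zeros(200, dtype=int))
        np.testing.assert_allclose(back, eta, atol=0.05)


class TestSpectrum:
    def test_white_noise_flat_spectrum(self):
        # oracle: flat spectrum of white noise; bin-averaged periodogram
        # deviations bounded by the chi-squared sampling distribution
        rng = np.random.default_rng(9)
        grid = VoxelGrid((64, 64, 1))
        t = 20
        eta = rng.standard_normal((64 * 64, t))
        sm = estimate_spectrum(eta, np.ones(t), grid)
        assert sm.density.mean() == pytest.approx(1.0)
        # average over frequency blocks of 256 bins x t frames
        blocks = sm.density.reshape(16, 256).mean(axis=1)
        se = 1.0 / np.sqrt(256 * t)
        assert np.abs(blocks - 1.0).max() < 4 * se * np.sqrt(2)

    def test_known_filter_spectrum_recovered(self):
        rng = np.random.default_rng(10)
        grid = VoxelGrid((32, 32, 1))
        fx = np.fft.fftfreq(32)
        lam_true = 1.0 / (1.0 + 20.0 * (fx[:, None] ** 2 + fx[None, :] ** 2))
        lam_true = lam_true / lam_true.mean()
        t = 200
        eta = np.empty((1024, t))
        for j in range(t):
            xi = rng.standard_normal((32, 32))
            eta[:, j] = np.real(
                np.fft.ifft2(np.sqrt(lam_true[:, :]) * np.fft.fft2(xi))
            ).ravel(order="F")
        sm = estimate_spectrum(eta, np.ones(t), grid)
        est = sm.density.reshape(32, 32)
        # radially pool into coarse bins to beat the chi-squared noise
        ratio = est.sum() / lam_true.sum()
        assert ratio == pytest.approx(1.0, rel=1e-6)
        rel = np.abs(est - lam_true) / lam_true
        assert np.median(rel) < 0.2

    def test_rho_zero_is_one(self):
        rng = np.random.default_rng(11)
        grid = VoxelGrid((8, 8, 1))
        sm = estimate_spectrum(rng.standard_normal((64, 5)), np.ones(5), grid)
        assert sm.autocorrelation.flat[0] == pytest.approx(1.0, abs=1e-12)

    def test_rho_symmetric_under_lag_negation(self):
        rng = np.random.default_rng(12)
        grid = VoxelGrid((16, 16, 1))
        sm = estimate_spectrum(rng.standard_normal((256, 6)), np.ones(6), grid)
        rho = sm.autocorrelation[:, :, 0]
        # rho(-h) = rho(h) for the full lag vector (both axes negated)
        neg = (16 - np.arange(16)) % 16
        np.testing.assert_allclose(rho, rho[np.ix_(neg, neg)], atol=1e-10)


class TestFitGlm:
    def test_generated_data_recovery(self):
        study, basis, truth = make_glm_study(nx=32, n_frames=20, sigma_scale=0.2, seed=13)
        fit = fit_glm(study, basis, l_bins=16)
        np.testing.assert_allclose(fit.phi, truth["phi"], rtol=0.08)
        assert np.median(fit.sigma / truth["sigma"]) == pytest.approx(1.0, abs=0.06)
        rel_alpha = np.abs(fit.alpha - truth["alpha"]).mean() / np.abs(truth["alpha"]).mean()
        assert rel_alpha < 0.1
        assert np.abs(fit.spectrum.density.mean() - 1.0) < 1e-12

    def test_phi_normalization_any_input(self, glm_fit):
        assert (glm_fit.phi**2).sum() == pytest.approx(glm_fit.n_frames, abs=1e-8)

    def test_h_mean_square_near_one_over_entries(self, glm_fit):
        ok = glm_fit.bins >= 0
        h_sq = glm_fit.qtransform.h[glm_fit.bins[ok]] ** 2
        assert h_sq.mean() == pytest.approx(1.0, abs=1e-2)

    def test_noiseless_refit_degenerates_gracefully(self, glm_study, glm_fit):
        study, basis, _ = glm_study
        clean = DynamicImage(glm_fit.zhat, study.grid, study.schedule)
        refit = fit_glm(clean, basis)
        np.testing.assert_allclose(refit.sigma, 0.0, atol=1e-8)
        np.testing.assert_allclose(refit.residuals, 0.0, atol=1e-8)

    def test_deterministic(self, glm_study):
        study, basis, _ = glm_study
        f1 = fit_glm(study, basis, l_bins=8)
        f2 = fit_glm(study, basis, l_bins=8)
        np.testing.assert_array_equal(f1.sigma, f2.sigma)
        np.testing.assert_array_equal(f1.eta, f2.eta)


class TestWlsSamplingProperties:
    def test_unbiasedness_over_replicates(self):
        # property: mean(alpha_hat) - alpha within 3 MC standard errors
        rng = np.random.default_rng(14)
        t, k = 30, 3
        x = np.column_stack([np.ones(t), np.linspace(0, 1, t), np.exp(-np.arange(t) / 6)])
        w = 0.5 + rng.random(t)
        alpha = np.array([2.0, -1.0, 3.0])
        reps = 300
        ests = np.empty((reps, k))
        for b in range(reps):
            z = (x @ alpha + 0.5 * rng.standard_normal(t))[None, :]
            ests[b], _ = wls_alpha(z, x, w)
        se = ests.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(ests.mean(axis=0) - alpha) < 3 * se)

    def test_covariance_matches_closed_form(self):
        # property: empirical covariance within 15% (Frobenius) of
        # sigma^2 [X'WX]^{-1} when weights are inverse variances
        rng = np.random.default_rng(15)
        t, k = 30, 2
        x = np.column_stack([np.ones(t), np.linspace(-1, 1, t)])
        sigma = 0.7
        w = np.full(t, 1.0 / sigma**2)
        reps = 2000
        ests = np.empty((reps, k))
        for b in range(reps):
            z = (x @ np.array([1.0, 2.0]) + sigma * rng.standard_normal(t))[None, :]
            ests[b], _ = wls_alpha(z, x, w)
        emp = np.cov(ests.T)
        ref = sigma**2 * coefficient_covariance(x, w) * w[0]  # w scaled to 1/sigma^2
        rel = np.linalg.norm(emp - ref) / np.linalg.norm(ref)
        assert rel < 0.15


class TestDiagnostics:
    def test_tables_shapes_and_consistency(self, glm_fit):
        d = residual_diagnostics(glm_fit)
        assert len(d["per_frame"]) == glm_fit.n_frames
        np.testing.assert_allclose(d["per_bin"]["h"].to_numpy(), glm_fit.qtransform.h)
        assert set(d["autocorrelation"]) == {"x", "y", "z"}

    def test_gaussian_data_frame_medians_near_zero(self):
        study, basis, _ = make_glm_study(nx=96, n_frames=16, seed=16)
        fit = fit_glm(study, basis, l_bins=8)
        d = residual_diagnostics(fit)
        assert np.abs(d["per_frame"]["q50"]).max() < 0.05

    def test_white_eta_autocorrelation_small_beyond_lag0(self, glm_fit):
        d = residual_diagnostics(glm_fit)
        prof = d["autocorrelation"]["x"]["rho"].to_numpy()
        assert prof[0] == pytest.approx(1.0)
        assert np.abs(prof[2:]).max() < 0.15
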