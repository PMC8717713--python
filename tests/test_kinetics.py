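import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petboot.bootstrap import BootstrapSet
from petboot.kinetics import (
    DEFAULT_T_B,
    PARAM_NAMES,
    KineticMaps,
    ResidueModel,
    TwoCompartmentParams,
    decompose_residue,
    element_summaries,
    fit_residue_model,
    kinetic_params,
    map_bootstrap_kinetics,
    nnls_map,
    residue_summaries,
    residue_tac,
    two_compartment_residue,
    voi_percentile_distribution,
)
from petboot.study import VOIMask


class TestTwoCompartmentResidue:
    def test_kety_schmidt_reduction(self):
        # with no trapping the residue is a single exponential k1 e^{-k2 t}
        p = TwoCompartmentParams(0.1, 0.2, 0.0, 0.0, 0.0)
        r = two_compartment_residue(p, t_end=20.0)
        np.testing.assert_allclose(r.values, 0.1 * np.exp(-0.2 * r.times), atol=1e-12)

    @pytest.mark.parametrize("t_b", [1.0 / 24, 1.0 / 12, 0.2])
    def test_vascular_pulse_integrates_to_fb(self, t_b):
        p = TwoCompartmentParams(0.0, 0.1, 0.0, 0.0, 0.12)
        r = two_compartment_residue(p, t_b=t_b, t_end=1.0, step=1e-4)
        mask = r.times <= t_b
        assert np.trapezoid(r.values[mask], r.times[mask]) == pytest.approx(0.12, rel=1e-3)

    def test_k4_zero_flux_closed_form(self):
        # oracle: symbolic small-t_b large-t_e limits of the summaries
        k1, k2, k3, fb = 0.15, 0.3, 0.08, 0.05
        p = TwoCompartmentParams(k1, k2, k3, 0.0, fb)
        lam1, lam2, pi = p.eigenrates
        assert lam2 == pytest.approx(0.0)
        r = two_compartment_residue(p, t_b=1e-3, t_end=400.0, step=1e-3)
        summ = residue_summaries(r, t_b=1e-3, t_e=400.0)
        key1 = (1 - fb) * k1
        assert summ["ki"] == pytest.approx(key1 * k3 / (k2 + k3), rel=1e-3)
        assert summ["kd"] == pytest.approx(key1 * k2 / (k2 + k3), rel=2e-3)
        assert summ["vb"] == pytest.approx(fb, rel=2e-3)
        assert summ["vd"] == pytest.approx(key1 * k2 / (k2 + k3) ** 2, rel=5e-3)

    def test_degenerate_eigenvalues_handled(self):
        p = TwoCompartmentParams(0.1, 0.0, 0.0, 0.0, 0.0)
        lam1, lam2, pi = p.eigenrates
        assert pi == 1.0
        r = two_compartment_residue(p, t_end=5.0)
        np.testing.assert_allclose(r.values, 0.1, atol=1e-12)

    def test_limit_error_decreases_linearly_in_tb(self):
        # property: the finite-t_b error of the summaries shrinks ~O(t_b)
        p = TwoCompartmentParams(0.12, 0.25, 0.06, 0.0, 0.04)
        errs = []
        for t_b in (0.08, 0.04, 0.02):
            r = two_compartment_residue(p, t_b=t_b, t_end=300.0, step=5e-4)
            s = residue_summaries(r, t_b=t_b, t_e=300.0)
            errs.append(abs(s["vb"] - 0.04))
        assert errs[1] < errs[0] and errs[2] < errs[1]
        assert errs[2] / errs[0] <= 0.3  # at least first-order in t_b


class TestDecomposeResidue:
    def test_constant_residue_pure_flux(self):
        t = np.linspace(0, 10, 1201)
        r = ResidueModel(times=t, values=np.full_like(t, 0.3))
        dec = decompose_residue(r, t_b=0.5, t_e=10.0)
        np.testing.assert_allclose(dec.r_e, 0.3)
        np.testing.assert_allclose(dec.r_b, 0.0, atol=1e-12)
        np.testing.assert_allclose(dec.r_d, 0.0, atol=1e-12)

    def test_exponential_symbolic_values(self):
        # oracle: symbolic evaluation for R(t) = exp(-t)
        t_b, t_e = 0.5, 8.0
        t = np.arange(0.0, t_e + 1e-4, 1e-4)
        r = ResidueModel(times=t, values=np.exp(-t))
        dec = decompose_residue(r, t_b, t_e)
        assert dec.r_e[0] == pytest.approx(np.exp(-t_e), rel=1e-6)
        assert dec.r_b[0] == pytest.approx(1 - np.exp(-t_b), rel=1e-6)
        assert dec.r_d[0] == pytest.approx(np.exp(-t_b) - np.exp(-t_e), rel=1e-6)

    def test_sum_identity_everywhere(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 5, 601)
        vals = np.sort(rng.random(t.size))[::-1]
        r = ResidueModel(times=t, values=vals)
        dec = decompose_residue(r, t_b=0.4, t_e=5.0)
        np.testing.assert_allclose(dec.r_b + dec.r_d + dec.r_e, r.values, atol=1e-12)

    def test_bad_bounds_rejected(self):
        t = np.linspace(0, 5, 601)
        r = ResidueModel(times=t, values=np.ones_like(t))
        with pytest.raises(ValueError):
            decompose_residue(r, t_b=5.0, t_e=1.0)


class TestResidueFit:
    def test_known_step_residue_recovered(self, aif, schedule20):
        # oracle: the generating 3-knot monotone step residue
        from petboot.kinetics import frame_averaged_convolution_basis

        knots = np.array([0.5, 3.0, 60.0])
        theta = np.array([0.05, 0.03, 0.02])
        t = np.arange(0.0, schedule20.end_time - 1e-9, 1.0 / 120)
        vals = (theta[None, :] * (t[:, None] <= knots[None, :])).sum(axis=1)
        gen = ResidueModel(times=t, values=vals)
        # oracle: exact frame-averaged forward convolution of the step residue
        tac = frame_averaged_convolution_basis(knots, aif, schedule20) @ theta
        fitted = fit_residue_model(
            tac, aif, schedule20, knots=np.array([0.5, 3.0, 60.0]), delay_grid=np.array([0.0])
        )
        rel = np.linalg.norm(fitted(t) - gen(t)) / np.linalg.norm(gen(t))
        assert rel <= 1e-3

    def test_patlak_case_constant_residue(self, aif, schedule20):
        from petboot.basis import patlak_column

        c = 0.04
        tac = c * patlak_column(aif, schedule20)
        fitted = fit_residue_model(tac, aif, schedule20, delay_grid=np.array([0.0]))
        late = fitted.times > 1.0
        np.testing.assert_allclose(fitted.values[late], c, rtol=0.05)

    def test_zero_tac_gives_zero_residue(self, aif, schedule20):
        fitted = fit_residue_model(np.zeros(20), aif, schedule20)
        np.testing.assert_allclose(fitted.values, 0.0, atol=1e-12)

    def test_short_aif_rejected(self, schedule20):
        from petboot.study import InputFunction

        short = InputFunction([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="cover"):
            fit_residue_model(np.ones(20), short, schedule20)


class TestNnlsMap:
    def test_exact_recovery_nonnegative_truth(self):
        rng = np.random.default_rng(1)
        x = np.abs(rng.random((12, 3)))
        alpha = np.abs(rng.random((30, 3)))
        z = alpha @ x.T
        est = nnls_map(z, x, np.ones(12))
        np.testing.assert_allclose(est, alpha, atol=1e-8)

    def test_negative_solution_clamped_active_set_oracle(self):
        # oracle: enumeration of active sets for K = 2
        x = np.column_stack([np.ones(6), np.linspace(0, 1, 6)])
        z = (2.0 - 3.0 * np.linspace(0, 1, 6))[None, :]  # unconstrained slope < 0
        w = np.ones(6)
        est = nnls_map(z, x, w)
        assert est[0, 1] == 0.0
        # best single-column fits
        cands = []
        for cols in ([0], [1], [0, 1]):
            xs = x[:, cols]
            beta, *_ = np.linalg.lstsq(xs, z[0], rcond=None)
            if np.all(beta >= 0):
                full = np.zeros(2)
                full[cols] = beta
                cands.append((np.sum((z[0] - x @ full) ** 2), full))
        cands.sort(key=lambda c: c[0])
        np.testing.assert_allclose(est[0], cands[0][1], atol=1e-10)

    def test_certificate_optimality_vs_random_candidates(self):
        rng = np.random.default_rng(2)
        x = rng.random((10, 4))
        z = rng.standard_normal((1, 10))
        w = 0.5 + rng.random(10)
        est = nnls_map(z, x, w)
        obj = np.sum(w * (z[0] - x @ est[0]) ** 2)
        for _ in range(100):
            cand = np.abs(rng.standard_normal(4))
            assert obj <= np.sum(w * (z[0] - x @ cand) ** 2) + 1e-10


def _summaries_from(values):
    return {k: np.asarray(v, dtype=float) for k, v in values.items()}


class TestKineticParams:
    def test_single_element_central_volume(self):
        summ = _summaries_from(
            {"vb": [0.0], "kd": [0.4], "vd": [2.0], "ki": [0.1], "delay": [0.0]}
        )
        maps = kinetic_params(np.array([[1.5]]), summ)
        assert maps.mtt[0] == pytest.approx(2.0 / 0.4)
        assert maps.k1[0] == pytest.approx(1.5 * 0.5)

    def test_equal_delays_constant_offset(self):
        summ = _summaries_from(
            {"vb": [0, 0], "kd": [0.3, 0.6], "vd": [1.0, 2.0], "ki": [0, 0], "delay": [0.25, 0.25]}
        )
        rng = np.random.default_rng(3)
        alpha = np.abs(rng.random((20, 2))) + 0.1
        maps = kinetic_params(alpha, summ)
        base = kinetic_params(alpha, {**summ, "delay": np.zeros(2)})
        np.testing.assert_allclose(maps.mtt - base.mtt, 0.25, atol=1e-12)

    def test_two_element_flow_weighted_average(self):
        # oracle: hand evaluation of the flow-weighted transit average
        summ = _summaries_from(
            {"vb": [0, 0], "kd": [0.2, 0.4], "vd": [1.0, 0.8], "ki": [0.05, 0.0], "delay": [0.1, 0.3]}
        )
        maps = kinetic_params(np.array([[1.0, 1.0]]), summ)
        w = np.array([0.2, 0.4]) / 0.6
        mtt_hand = w[0] * (0.1 + 1.0 / 0.2) + w[1] * (0.3 + 0.8 / 0.4)
        assert maps.mtt[0] == pytest.approx(mtt_hand)

    def test_zero_alpha_row_undefined_markers(self):
        summ = _summaries_from(
            {"vb": [0.1], "kd": [0.3], "vd": [1.0], "ki": [0.1], "delay": [0.0]}
        )
        maps = kinetic_params(np.zeros((1, 1)), summ)
        assert maps.vb[0] == 0 and maps.ki[0] == 0
        assert np.isnan(maps.mtt[0]) and np.isnan(maps.extraction[0])

    def test_k1_identity(self):
        rng = np.random.default_rng(4)
        summ = _summaries_from(
            {
                "vb": rng.random(3),
                "kd": rng.random(3),
                "vd": rng.random(3),
                "ki": rng.random(3),
                "delay": np.zeros(3),
            }
        )
        alpha = np.abs(rng.random((50, 3)))
        maps = kinetic_params(alpha, summ)
        np.testing.assert_allclose(maps.k1, maps.ki + maps.kd, atol=1e-14)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_maps_nonnegative_and_extraction_bounded(self, seed):
        rng = np.random.default_rng(seed)
        summ = _summaries_from(
            {
                "vb": rng.random(4),
                "kd": rng.random(4),
                "vd": rng.random(4),
                "ki": rng.random(4),
                "delay": rng.random(4),
            }
        )
        alpha = np.abs(rng.random((8, 4)))
        maps = kinetic_params(alpha, summ)
        for name in ("vb", "vd", "kd", "ki"):
            assert np.all(getattr(maps, name) >= 0)
        ex = maps.extraction[np.isfinite(maps.extraction)]
        assert np.all((ex >= 0) & (ex <= 1 + 1e-12))


class TestCombinationMonotonicity:
    def test_nonneg_combination_of_monotone_residues_is_monotone(self, aif, schedule20):
        rng = np.random.default_rng(5)
        residues = [
            two_compartment_residue(
                TwoCompartmentParams(0.1 * (k + 1), 0.2, 0.02 * k, 0.0, 0.02), t_end=61.0
            )
            for k in range(3)
        ]
        t = residues[0].times
        for _ in range(20):
            alpha = np.abs(rng.random(3))
            combo = sum(a * r.values for a, r in zip(alpha, residues))
            assert np.all(np.diff(combo) <= 1e-12)


class TestBootstrapKinetics:
    def test_identical_replicates_zero_sd(self, glm_fit):
        summ = _summaries_from(
            {
                "vb": [0.1, 0.0, 0.0],
                "kd": [0.0, 0.3, 0.1],
                "vd": [0.0, 1.5, 0.4],
                "ki": [0.0, 0.0, 0.05],
                "delay": [0.0, 0.0, 0.0],
            }
        )
        reps = [glm_fit.zhat.copy() for _ in range(4)]
        bset = BootstrapSet(kind="image", replicates=reps)
        _, _, sd = map_bootstrap_kinetics(bset, glm_fit.basis.design, glm_fit.w0, summ)
        for name in PARAM_NAMES:
            vals = sd[name][np.isfinite(sd[name])]
            np.testing.assert_allclose(vals, 0.0, atol=1e-10)

    def test_sd_maps_nonnegative(self, glm_fit):
        summ = _summaries_from(
            {
                "vb": [0.1, 0.0, 0.0],
                "kd": [0.0, 0.3, 0.1],
                "vd": [0.0, 1.5, 0.4],
                "ki": [0.0, 0.0, 0.05],
                "delay": [0.0, 0.0, 0.0],
            }
        )
        from petboot.bootstrap import image_bootstrap

        bset = image_bootstrap(glm_fit, 8, seed=0)
        _, _, sd = map_bootstrap_kinetics(bset, glm_fit.basis.design, glm_fit.w0, summ)
        for name in PARAM_NAMES:
            vals = sd[name][np.isfinite(sd[name])]
            assert np.all(vals >= 0)

    def test_single_voxel_linear_case_matches_wls_se(self):
        # oracle: closed-form WLS standard error propagated through the
        # (linear, interior) map for a distribution-volume-like element
        from petboot.basis import TemporalBasis
        from petboot.glm import fit_glm
        from petboot.bootstrap import image_bootstrap
        from petboot.study import DynamicImage, FrameSchedule, VoxelGrid

        rng = np.random.default_rng(6)
        t = 30
        sch = FrameSchedule(np.arange(t) + 0.5, np.ones(t))
        grid = VoxelGrid((1, 1, 1))
        x = (1.0 + np.linspace(0, 1, t))[:, None]
        sigma = 0.05
        alpha_true = 2.0
        z = (alpha_true * x[:, 0] + sigma * rng.standard_normal(t))[None, :]
        basis = TemporalBasis(design=x, names=["el"])
        fit = fit_glm(DynamicImage(z, grid, sch), basis, l_bins=1)
        bset = image_bootstrap(fit, 2000, seed=1)
        summ = _summaries_from({"vb": [0], "kd": [0], "vd": [3.0], "ki": [0], "delay": [0]})
        _, _, sd = map_bootstrap_kinetics(bset, basis.design, fit.w0, summ)
        w = fit.w0
        # model-implied per-frame variances under the fitted scales
        se_alpha = np.sqrt(
            (fit.sigma[0] ** 2)
            * np.sum(w**2 * x[:, 0] ** 2 * fit.phi**2)
            / np.sum(w * x[:, 0] ** 2) ** 2
        )
        assert sd["vd"][0] == pytest.approx(3.0 * se_alpha, rel=0.10)


class TestVOIPercentiles:
    def test_constant_map(self):
        mask = VOIMask(np.array([True, True, False, True]), "v")
        sample = voi_percentile_distribution([np.full(4, 2.5)] * 5, mask, 95)
        np.testing.assert_allclose(sample, 2.5)

    def test_q100_is_maximum(self):
        rng = np.random.default_rng(7)
        mask = VOIMask(np.ones(10, dtype=bool), "all")
        maps = [rng.random(10) for _ in range(3)]
        sample = voi_percentile_distribution(maps, mask, 100)
        np.testing.assert_allclose(sample, [m.max() for m in maps])

    def test_gaussian_order_statistic_spread(self):
        # oracle: direct order-statistic simulation
        rng = np.random.default_rng(8)
        n_vox, q = 200, 90
        mask = VOIMask(np.ones(n_vox, dtype=bool), "v")
        maps = [rng.standard_normal(n_vox) for _ in range(800)]
        sample = voi_percentile_distribution(maps, mask, q)
        ref = np.percentile(rng.standard_normal((4000, n_vox)), q, axis=1)
        assert sample.std() == pytest.approx(ref.std(), rel=0.15)
        assert sample.mean() == pytest.approx(ref.mean(), abs=0.05)

    def test_empty_mask_rejected(self):
        mask = VOIMask(np.array([True]), "v")
        with pytest.raises(ValueError):
            voi_percentile_distribution([np.array([np.nan])], mask, 50)
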