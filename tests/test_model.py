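"""Transform, Lindsey density, central matching, CE trace and selection."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from sebula.fragments import HclcTable
from sebula.model import (
    ConcavityError,
    InsufficientCellsError,
    ModelError,
    NullFit,
    SebulaModel,
    _elbow,
    boxcox_apply,
    boxcox_mle,
    cross_entropy,
    estimate_lambda,
    fit_mixture_density,
    fit_model,
    fit_null_central_matching,
    natural_spline_basis,
    robust_boxcox_lambda,
    select_xmin,
    truncate,
)
from sebula.simulate import SimConfig, hclc_table_from_sim, simulate_hclc


class TestTruncate:
    def test_zeros_always_excluded(self):
        x = np.array([0] * 300 + [1] * 200 + [5] * 100)
        values, n_ret, n_tot = truncate(x, 0)
        assert n_tot == 600 and n_ret == 300 and values.min() == 1

    def test_threshold_keeps_at_least(self):
        x = np.repeat([1, 2, 3, 4], 100)
        values, n_ret, _ = truncate(x, 3)
        assert set(values) == {3, 4} and n_ret == 200

    def test_insufficient_cells(self):
        with pytest.raises(InsufficientCellsError):
            truncate(np.arange(100), 99)

    def test_negative_xmin_rejected(self):
        with pytest.raises(ValueError):
            truncate(np.arange(300), -1)


class TestBoxCox:
    def test_lambda_one_is_shift(self):
        x = np.array([1.0, 2.0, 10.0])
        assert np.allclose(boxcox_apply(x, 1.0), x - 1)

    def test_lambda_zero_limit_is_log(self):
        x = np.array([1.0, 2.0, 10.0])
        assert np.allclose(boxcox_apply(x, 0.0), np.log(x))
        assert np.allclose(boxcox_apply(x, 1e-13), np.log(x))
        # continuity near zero
        assert np.allclose(boxcox_apply(x, 1e-6), np.log(x), atol=1e-4)

    def test_monotone(self):
        x = np.sort(np.random.default_rng(0).uniform(1, 100, 50))
        for lam in (-1.5, -0.3, 0.0, 0.4, 2.0):
            assert np.all(np.diff(boxcox_apply(x, lam)) > 0)

    def test_mle_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(3.0, 0.5, 5000)
        lam = boxcox_mle(x)
        grid = np.linspace(-2, 2, 401)
        llf = [stats.boxcox_llf(g, x) for g in grid]
        lam_grid = grid[int(np.argmax(llf))]
        assert abs(lam - lam_grid) < 0.05

    def test_degenerate_rejected(self):
        with pytest.raises(ModelError):
            boxcox_mle(np.full(100, 7.0))
        with pytest.raises(ValueError):
            boxcox_mle(np.array([0.0, 1.0]))


class TestRobustLambda:
    def test_contamination_stable(self):
        """The robust exponent barely moves when doublets are added."""
        rng = np.random.default_rng(2)
        r, m = 10.0, 40.0
        p = r / (r + m)
        sing = rng.negative_binomial(r, p, 9000).astype(float)
        doub = (
            rng.negative_binomial(r, p, 2000) + rng.negative_binomial(r, p, 2000)
        ).astype(float)
        clean = sing[sing > 0]
        mixed = np.concatenate([sing[:8000], doub])
        mixed = mixed[mixed > 0]
        lam_clean = robust_boxcox_lambda(clean)
        lam_mixed = robust_boxcox_lambda(mixed, pi0=0.8)
        assert abs(lam_clean - lam_mixed) < 0.15
        # the plain MLE, by contrast, is dragged far down by the mixture
        assert boxcox_mle(mixed) < lam_mixed - 0.2

    def test_normal_data_needs_no_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 5, 8000)
        lam = robust_boxcox_lambda(x[x > 0])
        z = boxcox_apply(x[x > 0], lam)
        assert abs(stats.skew(z)) < 0.1


class TestMixtureDensity:
    def test_matches_closed_form_normal(self):
        """Lindsey estimate tracks the true density within 0.02 sup-norm."""
        rng = np.random.default_rng(4)
        z = rng.normal(0, 1, 20_000)
        fit = fit_mixture_density(z)
        delta = fit.bin_width
        err = np.abs(fit.rho / delta - stats.norm.pdf(fit.centers))
        assert err.max() < 0.02

    def test_rho_sums_to_one(self):
        rng = np.random.default_rng(5)
        fit = fit_mixture_density(rng.gamma(3, 2, 5000))
        assert abs(fit.rho.sum() - 1.0) < 1e-9
        # trapezoid integral of the per-bin density is also ~1
        assert abs(np.trapezoid(fit.rho / fit.bin_width, fit.centers) - 1) < 0.05

    def test_cdf_monotone_zero_to_one(self):
        rng = np.random.default_rng(6)
        fit = fit_mixture_density(rng.normal(2, 3, 3000))
        grid = np.linspace(fit.centers[0] - 1, fit.centers[-1] + 1, 500)
        cdf = fit.cdf(grid)
        assert cdf[0] == 0.0 and cdf[-1] == 1.0
        assert np.all(np.diff(cdf) >= 0)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(7)
        fit = fit_mixture_density(rng.normal(0, 1, 10_000))
        grid = np.linspace(-6, 6, 4001)
        assert abs(np.trapezoid(fit.density(grid), grid) - 1) < 0.01

    def test_sparse_data_rejected(self):
        with pytest.raises(ModelError, match="sparse"):
            fit_mixture_density(np.array([0.0, 1.0] * 150), k=20, spline_df=7)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture_density(np.random.default_rng(0).normal(size=500), k=10)


def test_natural_spline_linear_beyond_boundaries():
    knots = np.linspace(0, 10, 8)
    left = natural_spline_basis(np.array([-5.0, -4.0, -3.0]), knots)
    right = natural_spline_basis(np.array([13.0, 14.0, 15.0]), knots)
    for block in (left, right):
        second_diff = block[2] - 2 * block[1] + block[0]
        assert np.allclose(second_diff, 0, atol=1e-8)


class TestCentralMatching:
    def test_quadratic_coefficient_algebra(self):
        # delta0 = c_max - b1/(2 b2), sigma0 = (-2 b2)^(-1/2)
        null = NullFit(
            c_max=3.0,
            quad=(0.0, 0.0, -0.5),
            delta0=3.0 - 0.0 / (2 * -0.5),
            sigma0=(-2 * -0.5) ** -0.5,
            pi0_hat=1.0,
            pi0_tilde=1.0,
            f_tilde=np.ones(3),
            window=(0.0, 6.0),
        )
        assert null.delta0 == 3.0 and null.sigma0 == 1.0

    def test_recovers_pure_normal(self):
        rng = np.random.default_rng(8)
        z = rng.normal(2.0, 0.7, 20_000)
        fit = fit_mixture_density(z)
        null = fit_null_central_matching(fit, z, len(z), len(z))
        assert abs(null.delta0 - 2.0) < 0.05
        assert abs(null.sigma0 - 0.7) < 0.05
        assert 0.9 <= null.pi0_hat <= 1.0

    def test_pi0_tilde_formula(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1, 10_000)
        fit = fit_mixture_density(z)
        full = fit_null_central_matching(fit, z, 10_000, 10_000)
        assert full.pi0_tilde == pytest.approx(full.pi0_hat)
        half = fit_null_central_matching(fit, z, 5_000, 10_000)
        assert half.pi0_tilde == pytest.approx(1 - 0.5 * (1 - half.pi0_hat))

    def test_convexity_rejected(self):
        """A bimodal valley in the central window has no concave peak."""
        rng = np.random.default_rng(10)
        z = np.concatenate(
            [rng.normal(0, 0.2, 3000), rng.normal(4, 0.2, 3000)]
        )
        fit = fit_mixture_density(z)
        with pytest.raises((ConcavityError, ModelError)):
            fit_null_central_matching(fit, z, len(z), len(z), refine=False)

    def test_refinement_silent_on_clean_null(self):
        rng = np.random.default_rng(11)
        z = rng.normal(5.0, 1.2, 15_000)
        fit = fit_mixture_density(z)
        plain = fit_null_central_matching(fit, z, len(z), len(z), refine=False)
        refined = fit_null_central_matching(fit, z, len(z), len(z), refine=True)
        assert abs(plain.delta0 - refined.delta0) < 0.05
        assert refined.pi0_hat > 0.9

    def test_refinement_recovers_pi0_under_contamination(self):
        rng = np.random.default_rng(12)
        z = np.concatenate(
            [rng.normal(0, 1, 8000), rng.normal(2.3, 1.1, 2000)]
        )
        fit = fit_mixture_density(z)
        plain = fit_null_central_matching(fit, z, len(z), len(z), refine=False)
        refined = fit_null_central_matching(fit, z, len(z), len(z), refine=True)
        assert abs(refined.pi0_hat - 0.8) <= abs(plain.pi0_hat - 0.8) + 0.01
        assert abs(refined.pi0_hat - 0.8) < 0.08


class TestCrossEntropy:
    def _null(self, delta0, sigma0):
        return NullFit(
            c_max=delta0,
            quad=(0.0, 0.0, -1 / (2 * sigma0**2)),
            delta0=delta0,
            sigma0=sigma0,
            pi0_hat=1.0,
            pi0_tilde=1.0,
            f_tilde=np.ones(3),
            window=(delta0 - 1, delta0 + 1),
        )

    def test_all_points_at_mean(self):
        sigma0 = 1.7
        null = self._null(0.0, sigma0)
        ce = cross_entropy(null, np.zeros(50))
        assert ce == pytest.approx(np.log(sigma0 * np.sqrt(2 * np.pi)))

    def test_toy_hand_computation(self):
        null = self._null(0.0, 1.0)
        ce = cross_entropy(null, np.array([-1.0, 0.0, 1.0]))
        assert ce == pytest.approx(np.log(np.sqrt(2 * np.pi)) + 1 / 3)

    def test_invariant_to_points_outside_band(self):
        null = self._null(0.0, 1.0)
        inside = np.array([-0.5, 0.2, 0.9])
        ce1 = cross_entropy(null, inside)
        ce2 = cross_entropy(null, np.concatenate([inside, [5.0, -17.0]]))
        assert ce1 == pytest.approx(ce2)

    def test_empty_band_raises(self):
        null = self._null(0.0, 0.5)
        with pytest.raises(ModelError, match="no observations"):
            cross_entropy(null, np.array([10.0, 12.0]))


class TestElbowSelection:
    def test_sharp_knee_found(self):
        grid = np.arange(11)
        ce = np.where(grid <= 4, 10.0 - 2.0 * grid, 2.0 - 0.05 * (grid - 4))
        assert _elbow(grid, ce) == 4

    def test_linear_trace_returns_first(self):
        grid = np.arange(8)
        assert _elbow(grid, 10.0 - grid.astype(float)) == 0

    def test_concave_plunge_returns_first(self):
        """Flat-then-plunging traces carry no diminishing-returns knee."""
        grid = np.arange(11)
        ce = np.where(grid <= 7, 5.0 - 0.01 * grid, 5.0 - 2.0 * (grid - 7))
        assert _elbow(grid, ce) == 0

    def test_nan_candidates_skipped(self):
        grid = np.arange(6)
        ce = np.array([8.0, np.nan, 4.0, 2.0, 1.9, 1.85])
        assert _elbow(grid, ce) in (2, 3)


class TestSelectXmin:
    def test_single_candidate(self, null_table):
        scan = select_xmin(null_table, grid=[0])
        assert scan.chosen == 0

    def test_scan_runs_and_records(self, sim20):
        _, table = sim20
        scan = select_xmin(table, grid=[0, 5, 10, 15])
        assert len(scan.grid) == 4
        assert np.isfinite(scan.ce).sum() >= 2
        assert scan.chosen in scan.grid
        assert scan.lam is not None


class TestFitModel:
    def test_full_fit_recovers_composition(self, sim20, model20):
        sim, _ = sim20
        est = 1 - model20.null.pi0_tilde
        assert abs(est - 0.2) < 0.08
        assert model20.null.quad[2] < 0

    def test_fixed_lambda_and_mle_policies(self, sim20):
        _, table = sim20
        m_fixed = fit_model(table, 0, lam=0.45)
        assert m_fixed.transform.lam == 0.45
        m_mle = fit_model(table, 0, lam="mle")
        vals, _, _ = truncate(table, 0)
        assert m_mle.transform.lam == pytest.approx(boxcox_mle(vals), abs=1e-6)

    def test_json_roundtrip_preserves_posteriors(self, sim20, model20, tmp_path):
        from sebula.classify import posterior_probs

        _, table = sim20
        path = tmp_path / "model.json"
        model20.to_json(path)
        back = SebulaModel.from_json(path)
        p1 = posterior_probs(table, model20)["posterior"].values
        p2 = posterior_probs(table, back)["posterior"].values
        assert np.allclose(p1, p2, atol=1e-9)

    def test_rank_of_posterior_follows_hclc(self, sim20, model20):
        """Monotone transform + monotone posterior preserve count order."""
        from sebula.classify import posterior_probs

        _, table = sim20
        post = posterior_probs(table, model20)
        kept = post[post["hclc"] > 0].sort_values("hclc")
        assert np.all(np.diff(kept["posterior"].values) >= 0)
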