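"""Matérn correlation, covariance, Laplace/MCMC inference, prediction."""

import math

import numpy as np
import pytest

from geocontracep.geodata import GeoPoint
from geocontracep.geostat import (
    BinomialDesign,
    MaternParams,
    ModelSpec,
    build_covariance,
    build_design,
    cluster_summaries,
    fit_laplace,
    fit_laplace_design,
    fit_mcmc,
    log_joint,
    matern_correlation,
    posterior_odds_ratios,
    predict_surface,
)
from geocontracep.synthetic import SimConfig, generate_survey


def random_points(rng, n, lon=(36.0, 42.0), lat=(6.0, 12.0)):
    return [GeoPoint(float(lo), float(la))
            for lo, la in zip(rng.uniform(*lon, n), rng.uniform(*lat, n))]


def intercept_design(rng, m=20, n_i=30, p_use=0.4, special=None):
    """Intercept-only binomial design over m random cluster locations."""
    pts = random_points(rng, m)
    n = np.full(m, n_i, dtype=float)
    y = rng.binomial(n_i, p_use, size=m).astype(float)
    if special is not None:
        idx, n_sp, y_sp = special
        n[idx], y[idx] = n_sp, y_sp
    return BinomialDesign(
        X=np.ones((m, 1)), y=y, n=n, ea_index=np.arange(m),
        ea_ids=[f"EA{i:02d}" for i in range(m)], ea_locations=pts,
        colnames=["intercept"],
    )


class TestMaternCorrelation:
    u = np.array([0.1, 0.5, 1, 2, 5, 10, 20, 50, 100, 200, 500])

    def test_zero_lag_is_one(self):
        assert matern_correlation(0.0, 10.0, 1.0) == 1.0
        assert matern_correlation(0.0, 1.0, 0.5) == 1.0

    @pytest.mark.parametrize("phi", [1.0, 10.0, 150.0])
    def test_exponential_special_case(self, phi):
        # kappa = 1/2: rho(u) = exp(-u/phi)
        got = matern_correlation(self.u, phi, 0.5)
        np.testing.assert_allclose(got, np.exp(-self.u / phi), atol=1e-10)

    @pytest.mark.parametrize("phi", [1.0, 10.0, 150.0])
    def test_kappa_three_halves_closed_form(self, phi):
        t = self.u / phi
        np.testing.assert_allclose(
            matern_correlation(self.u, phi, 1.5), (1 + t) * np.exp(-t), atol=1e-10)

    @pytest.mark.parametrize("phi", [1.0, 10.0, 150.0])
    def test_kappa_five_halves_closed_form(self, phi):
        t = self.u / phi
        expected = (1 + t + t**2 / 3.0) * np.exp(-t)
        np.testing.assert_allclose(
            matern_correlation(self.u, phi, 2.5), expected, atol=1e-10)

    def test_specific_values(self):
        assert matern_correlation(2.0, 1.0, 0.5) == pytest.approx(
            math.exp(-2.0), abs=1e-10)
        assert matern_correlation(1.0, 1.0, 1.5) == pytest.approx(
            2.0 * math.exp(-1.0), abs=1e-10)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 1.5, 2.5])
    def test_monotone_decreasing_in_unit_interval(self, kappa):
        vals = matern_correlation(np.linspace(0, 400, 300), 60.0, kappa)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals > 0) and np.all(vals <= 1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            matern_correlation(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            matern_correlation(1.0, 1.0, 0.0)


class TestBuildCovariance:
    def test_single_point(self):
        cov = build_covariance([GeoPoint(38.0, 9.0)], MaternParams(2.5, 10.0))
        assert cov.shape == (1, 1)
        assert cov[0, 0] == pytest.approx(2.5, rel=1e-7)

    def test_diagonal_is_variance_plus_jitter(self, rng):
        params = MaternParams(3.0, 50.0, 1.0)
        cov = build_covariance(random_points(rng, 15), params)
        np.testing.assert_allclose(np.diag(cov), 3.0 * (1 + 1e-8), rtol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        from geocontracep.geodata import haversine_km

        pts = random_points(rng, 20)
        params = MaternParams(1.7, 80.0, 1.0)
        cov = build_covariance(pts, params)
        for i in range(20):
            for j in range(20):
                u = haversine_km(pts[i], pts[j])
                expected = params.sigma2 * matern_correlation(u, 80.0, 1.0)
                if i == j:
                    expected += 1e-8 * params.sigma2
                assert cov[i, j] == pytest.approx(expected, abs=1e-12)

    def test_positive_semidefinite_on_random_sets(self, rng):
        for n in (10, 50, 150):
            cov = build_covariance(random_points(rng, n), MaternParams(1.0, 120.0))
            eigmin = np.linalg.eigvalsh(cov).min()
            assert eigmin >= -1e-8


class TestLogJoint:
    def _tiny_design(self, rng, m=5):
        pts = random_points(rng, m)
        X = np.column_stack([np.ones(3 * m), rng.integers(0, 2, 3 * m)])
        return BinomialDesign(
            X=X, y=rng.integers(0, 4, 3 * m).astype(float),
            n=np.full(3 * m, 5.0), ea_index=np.repeat(np.arange(m), 3),
            ea_ids=[f"E{i}" for i in range(m)], ea_locations=pts,
            colnames=["intercept", "x"],
        )

    def test_closed_form_at_zero_eta(self, rng):
        m = 4
        pts = random_points(rng, m)
        design = BinomialDesign(
            X=np.ones((m, 1)), y=np.full(m, 3.0), n=np.full(m, 6.0),
            ea_index=np.arange(m), ea_ids=[f"E{i}" for i in range(m)],
            ea_locations=pts, colnames=["intercept"],
        )
        from geocontracep.geostat import binomial_loglik

        # eta = 0 gives sum_i [y*0 - n log 2]
        assert binomial_loglik(design.y, design.n, np.zeros(m)) == pytest.approx(
            -6.0 * m * math.log(2.0), abs=1e-12)

    def test_intercept_field_shift_invariance(self, rng):
        from geocontracep.geostat import binomial_loglik

        design = self._tiny_design(rng)
        gamma = np.array([0.3, -0.2])
        S = rng.standard_normal(5)
        c = 0.83
        eta1 = design.X @ gamma + S[design.ea_index]
        gamma2 = gamma + np.array([c, 0.0])
        eta2 = design.X @ gamma2 + (S - c)[design.ea_index]
        assert binomial_loglik(design.y, design.n, eta1) == pytest.approx(
            binomial_loglik(design.y, design.n, eta2), abs=1e-10)

    def test_matches_per_term_oracle(self, rng):
        design = self._tiny_design(rng)
        spec = ModelSpec(factors=(), prior_sd_beta=5.0)
        gamma = rng.standard_normal(2) * 0.5
        S = rng.standard_normal(5) * 0.3
        theta = (0.2, 3.0)
        got = log_joint(design, gamma, S, theta, spec)
        # independent brute-force summation of every term
        from scipy.stats import multivariate_normal, norm as norm_dist

        eta = design.X @ gamma + S[design.ea_index]
        ll = sum(y * e - n * math.log(1 + math.exp(e))
                 for y, n, e in zip(design.y, design.n, eta))
        lp_g = sum(norm_dist.logpdf(g, 0, 5.0) for g in gamma)
        cov = build_covariance(design.ea_locations,
                               MaternParams(math.exp(0.2), math.exp(3.0), spec.kappa))
        lp_s = multivariate_normal.logpdf(S, mean=np.zeros(5), cov=cov)
        lp_t = (norm_dist.logpdf(0.2, 0, 2) + norm_dist.logpdf(3.0, 0, 2))
        assert got == pytest.approx(ll + lp_g + lp_s + lp_t, abs=1e-8)

    def test_dimension_mismatch_errors(self, rng):
        design = self._tiny_design(rng)
        with pytest.raises(ValueError):
            log_joint(design, np.zeros(3), np.zeros(5), (0, 0), ModelSpec())


class TestFitLaplace:
    def test_no_spatial_limit_matches_glm(self, small_survey):
        """With the field variance pinned to ~0 the fit reduces to penalised
        logistic regression; compare with an IRLS (statsmodels GLM) oracle."""
        import statsmodels.api as sm

        spec = ModelSpec(
            factors=("wealth", "partner_discussion", "education"),
            prior_sd_beta=100.0,
            hyper_mean=(-12.0, 0.0), hyper_sd=(1e-6, 1e-6),
            grid_res=1, grid_halfwidth=0.0,
        )
        design = build_design(small_survey.women, spec)
        fit = fit_laplace_design(design, spec)
        glm = sm.GLM(np.column_stack([design.y, design.n - design.y]), design.X,
                     family=sm.families.Binomial()).fit()
        tab = fit.coef_table.set_index("coefficient")
        for k, name in enumerate(design.colnames):
            assert abs(tab.loc[name, "mean"] - glm.params[k]) < 2.0 * glm.bse[k]

    def test_single_seed_recovery_of_strong_effect(self, default_survey):
        spec = ModelSpec(grid_res=9)
        fit = fit_laplace(default_survey.women, spec,
                          ea_locations=default_survey.ea_centroids)
        tab = fit.coef_table.set_index("coefficient")
        row = tab.loc["partner_discussion:yes"]
        # single realization: the strong effect is clearly detected and of
        # the right magnitude (calibration is checked over 25 replicates in
        # the acceptance suite)
        assert row["q2.5"] > 2.0
        assert abs(row["mean"] - 3.01) < 0.5
        assert (fit.coef_table["q2.5"] <= fit.coef_table["mean"]).all()
        assert (fit.coef_table["mean"] <= fit.coef_table["q97.5"]).all()
        w = np.array([n["weight"] for n in fit.nodes])
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_prior_sensitivity_small_on_identified_fit(self, small_survey):
        base = ModelSpec(factors=("wealth", "partner_discussion"), grid_res=7)
        wide = ModelSpec(factors=("wealth", "partner_discussion"), grid_res=7,
                         prior_sd_beta=20.0, hyper_sd=(4.0, 4.0),
                         grid_halfwidth=1.5)  # same grid span, doubled prior sd
        f1 = fit_laplace(small_survey.women, base)
        f2 = fit_laplace(small_survey.women, wide)
        t1 = f1.coef_table.set_index("coefficient")["mean"]
        t2 = f2.coef_table.set_index("coefficient")["mean"]
        for name in ("wealth:middle", "wealth:high", "partner_discussion:yes"):
            assert abs(t1[name] - t2[name]) < 0.05

    def test_too_few_clusters_rejected(self):
        real = generate_survey(SimConfig(seed=2, n_ea=5,
                                         women_in_need_per_ea_mean=5.0, n_sdp=10))
        with pytest.raises(ValueError, match="clusters"):
            fit_laplace(real.women, ModelSpec(factors=("wealth",)))

    def test_rank_deficient_design_rejected(self, small_survey):
        # duplicating a factor aliases its dummies
        spec = ModelSpec(factors=("wealth", "wealth"))
        with pytest.raises(ValueError, match="rank"):
            build_design(small_survey.women, spec)


class TestClusterSummaries:
    def test_counts_and_ordering(self, small_survey):
        clusters = cluster_summaries(small_survey.women,
                                     small_survey.ea_centroids)
        assert [c.ea_id for c in clusters] == sorted({w.ea_id for w in
                                                      small_survey.women})
        total_y = sum(c.y_i for c in clusters)
        assert total_y == sum(w.uses_modern for w in small_survey.women)
        for c in clusters:
            assert 0 <= c.y_i <= c.n_i


class TestMcmc:
    def test_seed_determinism(self, rng):
        design = intercept_design(rng, m=10)
        a = fit_mcmc(design, ModelSpec(grid_res=3), n_iter=2000, seed=5)
        b = fit_mcmc(design, ModelSpec(grid_res=3), n_iter=2000, seed=5)
        np.testing.assert_array_equal(a.gamma_samples, b.gamma_samples)
        np.testing.assert_array_equal(a.theta_samples, b.theta_samples)

    def test_prior_only_run_recovers_prior(self):
        design = BinomialDesign(
            X=np.zeros((0, 2)), y=np.zeros(0), n=np.zeros(0),
            ea_index=np.zeros(0, dtype=int), ea_ids=[], ea_locations=[],
            colnames=["a", "b"],
        )
        spec = ModelSpec(factors=(), prior_sd_beta=1.0)
        res = fit_mcmc(design, spec, n_iter=6000, seed=9)
        for k in range(2):
            assert abs(res.gamma_samples[:, k].mean()) < 0.1  # 0.1 prior sd
            assert res.gamma_samples[:, k].std() == pytest.approx(1.0, abs=0.15)

    def test_minimum_iterations_enforced(self, rng):
        with pytest.raises(ValueError):
            fit_mcmc(intercept_design(rng), n_iter=500)


class TestPredictSurface:
    def test_concentrates_at_large_n_data_location(self, rng):
        design = intercept_design(rng, m=25, n_i=40, p_use=0.35,
                                  special=(0, 5000.0, 2000.0))
        fit = fit_laplace_design(design, ModelSpec(factors=(), grid_res=9))
        surf = predict_surface(fit, [design.ea_locations[0]], n_draws=2000, seed=1)
        assert surf.mean[0] == pytest.approx(0.4, abs=0.02)

    def test_reverts_to_mean_far_from_data(self, rng):
        from scipy.special import expit

        design = intercept_design(rng, m=20, n_i=50, p_use=0.3)
        fit = fit_laplace_design(design, ModelSpec(factors=(), grid_res=9))
        far = [GeoPoint(-120.0, -40.0)]  # thousands of km from all clusters
        surf = predict_surface(fit, far, n_draws=4000, seed=2)
        assert abs(surf.field_mean[0]) < 0.1
        gamma0 = fit.coef_table["mean"].iloc[0]
        # mean prevalence near the inverse logit of the non-spatial predictor
        assert surf.mean[0] == pytest.approx(float(expit(gamma0)), abs=0.1)

    def test_bands_monotone_everywhere(self, rng):
        design = intercept_design(rng, m=15)
        fit = fit_laplace_design(design, ModelSpec(factors=(), grid_res=7))
        lattice = random_points(rng, 50)
        surf = predict_surface(fit, lattice, n_draws=500, seed=3)
        assert np.all(surf.q025 <= surf.mean + 1e-12)
        assert np.all(surf.mean <= surf.q975 + 1e-12)
        assert np.all((surf.q025 >= 0) & (surf.q975 <= 1))


class TestPosteriorOddsRatios:
    def test_exp_of_log_odds_summaries(self, rng):
        design = intercept_design(rng, m=12)
        fit = fit_laplace_design(design, ModelSpec(factors=(), grid_res=5))
        por = posterior_odds_ratios(fit)
        np.testing.assert_allclose(por["por_mean"], np.exp(por["mean"]), rtol=1e-12)
        np.testing.assert_allclose(por["por_q2.5"], np.exp(por["q2.5"]), rtol=1e-12)

    def test_zero_coefficient_gives_unit_odds(self):
        assert round(math.exp(0.0), 2) == 1.0
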