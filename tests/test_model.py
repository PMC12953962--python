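import math

import numpy as np
import pytest
from scipy import stats

from otobayes import (
    ModelParams,
    ModelSpec,
    PosteriorDraws,
    PriorConfig,
    ValidationError,
    build_model_spec,
    convergence_report,
    ess,
    invlogit,
    log_likelihood,
    log_prior,
    probability_of_sparing,
    rhat,
    sample_posterior,
    summarize_vector,
)


def simple_spec(y, provinces=None, X=None, prior=None, **kw):
    y = np.asarray(y, float)
    n = y.size
    return ModelSpec(
        y=y,
        X=np.zeros((n, 0)) if X is None else np.asarray(X, float),
        provinces=np.zeros(n, int) if provinces is None else np.asarray(provinces, int),
        prior=prior or PriorConfig(),
        **kw,
    )


class TestLogLikelihood:
    def test_all_zero_params_give_half_probability(self):
        spec = simple_spec([1, 0, 1, 1, 0])
        params = ModelParams(alpha=0.0, beta=np.zeros(0), sigma=1.0, b=np.zeros(1))
        assert log_likelihood(params, spec) == pytest.approx(5 * math.log(0.5))

    def test_single_observation_closed_form(self):
        spec = simple_spec([1])
        params = ModelParams(alpha=0.45, beta=np.zeros(0), sigma=1.0, b=np.zeros(1))
        assert log_likelihood(params, spec) == pytest.approx(math.log(invlogit(0.45)))

    def test_extreme_eta_is_finite(self):
        spec = simple_spec([1, 0])
        up = ModelParams(alpha=1000.0, beta=np.zeros(0), sigma=1.0, b=np.zeros(1))
        down = ModelParams(alpha=-1000.0, beta=np.zeros(0), sigma=1.0, b=np.zeros(1))
        assert np.isfinite(log_likelihood(up, spec))
        assert np.isfinite(log_likelihood(down, spec))

    def test_cell_aggregation_matches_per_row_sum(self):
        rng = np.random.default_rng(0)
        n = 60
        X = (rng.random((n, 2)) < 0.4).astype(float)
        prov = rng.integers(0, 4, n)
        y = (rng.random(n) < 0.6).astype(float)
        spec = ModelSpec(y=y, X=X, provinces=prov, prior=PriorConfig())
        params = ModelParams(alpha=0.3, beta=np.array([0.5, -0.7]), sigma=1.0,
                             b=np.array([0.1, -0.2, 0.0, 0.4]))
        eta = 0.3 + X @ params.beta + params.b[prov]
        direct = float(np.sum(y * eta - np.logaddexp(0, eta)))
        assert log_likelihood(params, spec) == pytest.approx(direct, rel=1e-12)

    def test_dimension_mismatch(self):
        spec = simple_spec([1, 0])
        params = ModelParams(alpha=0.0, beta=np.array([1.0]), sigma=1.0, b=np.zeros(1))
        with pytest.raises(ValidationError):
            log_likelihood(params, spec)


class TestLogPrior:
    def test_matches_term_by_term_oracle(self):
        prior = PriorConfig()
        params = ModelParams(
            alpha=prior.intercept_mean, beta=np.array([0.2, -0.1]), sigma=1.0,
            b=np.array([0.3, -0.4, 0.0]),
        )
        oracle = (
            stats.norm.logpdf(params.alpha, prior.intercept_mean, prior.intercept_sd)
            + stats.norm.logpdf(params.beta, 0.0, prior.coef_sd).sum()
            + stats.expon.logpdf(params.sigma, scale=1.0 / prior.re_sd_rate)
            + stats.norm.logpdf(params.b, 0.0, params.sigma).sum()
        )
        assert log_prior(params, prior) == pytest.approx(float(oracle), rel=1e-12)

    def test_monotone_in_province_effect_magnitude(self):
        prior = PriorConfig()
        small = ModelParams(0.0, np.zeros(0), 1.0, np.array([0.5]))
        big = ModelParams(0.0, np.zeros(0), 1.0, np.array([1.0]))
        assert log_prior(big, prior) < log_prior(small, prior)

    def test_sigma_to_zero_limit(self):
        prior = PriorConfig()
        lps = [
            log_prior(ModelParams(0.0, np.zeros(0), s, np.array([0.5])), prior)
            for s in (0.1, 0.01, 0.001)
        ]
        assert lps[0] > lps[1] > lps[2]
        assert log_prior(ModelParams(0.0, np.zeros(0), -1.0, np.array([0.5])), prior) == -math.inf
        assert log_prior(ModelParams(0.0, np.zeros(0), 0.0, np.array([0.5])), prior) == -math.inf


class TestSampler:
    def test_no_data_posterior_matches_prior(self, prior):
        spec = simple_spec([], provinces=np.zeros(0, int))
        draws = sample_posterior(spec, 2, 500, 2000, seed=4)
        alpha = draws.stacked("alpha")
        se = prior.intercept_sd / math.sqrt(200)  # generous MC error bound
        assert abs(alpha.mean() - prior.intercept_mean) < 3 * se
        assert abs(alpha.std() - prior.intercept_sd) < 0.15

    def test_quadrature_equivalence_sigma_zero(self):
        # pure logistic model: sigma forced to ~0 by a huge exponential rate;
        # 1-D quadrature over alpha is the independent oracle
        prior = PriorConfig(re_sd_rate=1e8)
        y = np.r_[np.ones(73), np.zeros(23)]
        spec = simple_spec(y, prior=prior, province_labels=("P0",))
        draws = sample_posterior(spec, 4, 1000, 1500, seed=2)
        mcmc_mean = float(np.mean(invlogit(draws.stacked("alpha"))))

        grid = np.linspace(-5, 5, 4001)
        loglik = 73 * grid - 96 * np.logaddexp(0, grid)
        logp = loglik + stats.norm.logpdf(grid, 0.4473, 1.18)
        w = np.exp(logp - logp.max())
        w /= np.trapezoid(w, grid)
        oracle = float(np.trapezoid(w * invlogit(grid), grid))
        assert mcmc_mean == pytest.approx(oracle, abs=0.01)

    def test_seed_determinism_bitwise(self, complete_margins, prior):
        spec = build_model_spec(complete_margins, [], prior)
        a = sample_posterior(spec, 2, 100, 100, seed=9)
        b = sample_posterior(spec, 2, 100, 100, seed=9)
        for name in a.param_names:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_sigma_positive_in_every_draw(self, complete_margins, prior):
        spec = build_model_spec(complete_margins, [], prior)
        draws = sample_posterior(spec, 2, 200, 300, seed=3)
        assert np.all(draws.stacked("sigma") > 0)

    def test_exchangeability_of_observation_order(self, prior):
        rng = np.random.default_rng(8)
        n = 50
        y = (rng.random(n) < 0.7).astype(float)
        prov = rng.integers(0, 3, n)
        perm = rng.permutation(n)
        spec1 = simple_spec(y, provinces=prov, prior=prior)
        spec2 = simple_spec(y[perm], provinces=prov[perm], prior=prior)
        params = ModelParams(0.2, np.zeros(0), 0.8, np.array([0.1, -0.3, 0.2]))
        assert log_likelihood(params, spec1) == pytest.approx(
            log_likelihood(params, spec2), rel=1e-12
        )
        d1 = sample_posterior(spec1, 2, 300, 500, seed=5)
        d2 = sample_posterior(spec2, 2, 300, 500, seed=5)
        np.testing.assert_array_equal(d1.draws["alpha"], d2.draws["alpha"])

    def test_zero_covariate_column_leaves_functionals_unchanged(self, prior):
        rng = np.random.default_rng(11)
        n = 80
        y = (rng.random(n) < 0.7).astype(float)
        prov = rng.integers(0, 4, n)
        base = simple_spec(y, provinces=prov, prior=prior)
        with_zero = ModelSpec(
            y=y, X=np.zeros((n, 1)), provinces=prov, prior=prior,
            covariate_names=("null",),
        )
        d0 = sample_posterior(base, 2, 500, 1000, seed=6)
        d1 = sample_posterior(with_zero, 2, 500, 1000, seed=6)
        p0 = float(np.mean(invlogit(d0.stacked("alpha"))))
        p1 = float(np.mean(invlogit(d1.stacked("alpha"))))
        assert p0 == pytest.approx(p1, abs=0.02)
        # the dangling coefficient reverts to its prior
        beta = d1.stacked("beta[null]")
        assert abs(beta.mean()) < 0.05
        assert beta.std() == pytest.approx(0.5, abs=0.06)

    def test_single_chain_rejected(self, prior):
        with pytest.raises(ValidationError):
            sample_posterior(simple_spec([1.0]), n_chains=1)

    def test_parameter_recovery_single_large_fit(self, prior):
        # n=2000, 10 provinces, known truth: posterior mean within 3 SD
        from otobayes import SyntheticConfig, generate

        cfg = SyntheticConfig(
            n_respondents=2000, true_alpha=0.45,
            true_betas={"subspecialty": 0.8}, true_sigma=0.5, seed=13,
        )
        dataset, truth = generate(cfg)
        spec = build_model_spec(dataset, ["subspecialty"], prior)
        draws = sample_posterior(spec, 2, 600, 1000, seed=13)
        for name, true_val in (
            ("alpha", truth.alpha),
            ("beta[subspecialty]", truth.betas["subspecialty"]),
            ("sigma", truth.sigma),
        ):
            v = draws.stacked(name)
            assert abs(v.mean() - true_val) < 3 * v.std(), name


class TestDiagnostics:
    def _fake_draws(self, arrays: dict) -> PosteriorDraws:
        return PosteriorDraws(
            draws={k: np.asarray(v, float) for k, v in arrays.items()},
            seed=0, n_warmup=0,
            acceptance=np.full(next(iter(arrays.values())).shape[0], 0.3),
        )

    def test_iid_chains_rhat_near_one(self):
        rng = np.random.default_rng(21)
        d = self._fake_draws({"x": rng.normal(size=(4, 2000))})
        assert 0.99 <= rhat(d)["x"] <= 1.01
        # iid draws: ESS close to the nominal draw count
        assert ess(d)["x"] > 0.75 * 8000

    def test_separated_constant_chains_blow_up(self):
        d = self._fake_draws({"x": np.vstack([np.zeros(100), np.full(100, 10.0)])})
        assert rhat(d)["x"] > 1.1

    def test_identical_constant_chains_degenerate_warning(self):
        d = self._fake_draws({"x": np.zeros((2, 100))})
        with pytest.warns(UserWarning, match="degenerate"):
            rep = convergence_report(d)
        assert rep.rhat["x"] == 1.0
        assert "x" in rep.degenerate

    def test_autocorrelated_chain_has_lower_ess(self):
        rng = np.random.default_rng(22)
        iid = rng.normal(size=(2, 4000))
        ar = np.empty_like(iid)
        ar[:, 0] = iid[:, 0]
        for t in range(1, 4000):
            ar[:, t] = 0.9 * ar[:, t - 1] + math.sqrt(1 - 0.81) * iid[:, t]
        e_iid = ess(self._fake_draws({"x": iid}))["x"]
        e_ar = ess(self._fake_draws({"x": ar}))["x"]
        # AR(1) with rho=0.9 has ESS ~ N*(1-rho)/(1+rho) ~ N/19
        assert e_ar < e_iid / 8
        assert e_ar == pytest.approx(8000 / 19, rel=0.5)


class TestSummaries:
    def test_constant_draws(self):
        m, lo, hi = summarize_vector(np.full(100, 3.5))
        assert m == lo == hi == 3.5

    def test_linear_interpolation_quantiles(self):
        v = np.arange(1.0, 1001.0)
        m, lo, hi = summarize_vector(v, 0.90)
        assert lo == pytest.approx(50.95)
        assert hi == pytest.approx(950.05)

    def test_interval_nesting(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=5000)
        _, lo90, hi90 = summarize_vector(v, 0.90)
        _, lo95, hi95 = summarize_vector(v, 0.95)
        assert lo95 <= lo90 and hi90 <= hi95

    def test_bad_level(self):
        with pytest.raises(ValidationError):
            summarize_vector(np.ones(10), level=0.0)


class TestProbabilityOfSparing:
    def _draws(self, alpha, sigma):
        C, N = 2, len(alpha) // 2
        return PosteriorDraws(
            draws={
                "alpha": np.asarray(alpha, float).reshape(C, N),
                "sigma": np.asarray(sigma, float).reshape(C, N),
            },
            seed=0, n_warmup=0, acceptance=np.array([0.3, 0.3]),
        )

    def test_zero_alpha_gives_half(self):
        d = self._draws(np.zeros(100), np.full(100, 0.5))
        assert np.all(probability_of_sparing(d, "median_province") == 0.5)

    def test_modes_agree_with_degenerate_re(self):
        d = self._draws(np.full(100, 0.45), np.zeros(100))
        np.testing.assert_allclose(
            probability_of_sparing(d, "median_province"),
            probability_of_sparing(d, "new_province", seed=3),
        )

    def test_new_province_shrinks_toward_half(self):
        # logit-normal mean with mu=0.45, sigma=1 lies below invlogit(0.45)
        d = self._draws(np.full(200_000, 0.45), np.ones(200_000))
        marginal = probability_of_sparing(d, "new_province", seed=4)
        assert marginal.mean() < invlogit(0.45)
        assert marginal.mean() > 0.5

    def test_draws_csv_roundtrip(self, complete_margins, prior):
        spec = build_model_spec(complete_margins, ["age"], prior)
        draws = sample_posterior(spec, 2, 50, 60, seed=2)
        import io, tempfile, os
        from pathlib import Path

        with tempfile.TemporaryDirectory() as td:
            path = Path(td) / "draws.csv"
            draws.save_csv(path)
            back = PosteriorDraws.load_csv(path)
            for name in draws.param_names:
                np.testing.assert_array_equal(back.draws[name], draws.draws[name])
            # bit-identical files under the same seed
            draws2 = sample_posterior(spec, 2, 50, 60, seed=2)
            path2 = Path(td) / "draws2.csv"
            draws2.save_csv(path2)
            assert path.read_bytes() == path2.read_bytes()
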