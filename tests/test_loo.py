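import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from otobayes import (
    ModelSpec,
    PriorConfig,
    SyntheticConfig,
    ValidationError,
    build_model_spec,
    compare_models,
    exact_refit_loo,
    fit_generalized_pareto,
    generate,
    pointwise_loglik,
    psis_loo,
    sample_posterior,
    smooth_importance_weights,
)


class TestPointwiseLoglik:
    def _draws_and_spec(self, n_obs=6, n_draws=40, seed=0):
        rng = np.random.default_rng(seed)
        y = (rng.random(n_obs) < 0.6).astype(float)
        prov = rng.integers(0, 2, n_obs)
        spec = ModelSpec(y=y, X=np.zeros((n_obs, 0)), provinces=prov,
                         prior=PriorConfig(), province_labels=("A", "B"))
        draws = sample_posterior(spec, 2, 50, n_draws // 2, seed=seed)
        return draws, spec

    def test_zero_params_give_log_half(self):
        from otobayes import PosteriorDraws

        d = PosteriorDraws(
            draws={"alpha": np.zeros((2, 5)), "sigma": np.ones((2, 5)),
                   "b[A]": np.zeros((2, 5))},
            seed=0, n_warmup=0, acceptance=np.array([0.3, 0.3]),
            province_labels=("A",),
        )
        spec = ModelSpec(y=np.array([1.0, 0.0, 1.0]), X=np.zeros((3, 0)),
                         provinces=np.zeros(3, int), prior=PriorConfig(),
                         province_labels=("A",))
        ll = pointwise_loglik(d, spec)
        np.testing.assert_allclose(ll, math.log(0.5))

    def test_row_sums_equal_total_loglik(self):
        from otobayes import ModelParams, log_likelihood

        draws, spec = self._draws_and_spec()
        ll = pointwise_loglik(draws, spec)
        alpha, beta, sigma, b = draws.param_arrays()
        for k in (0, 7, 19):
            params = ModelParams(alpha[k], beta[k], sigma[k], b[k])
            assert ll[k].sum() == pytest.approx(log_likelihood(params, spec), rel=1e-12)

    def test_hand_computed_two_obs_three_draws(self):
        from otobayes import PosteriorDraws, invlogit

        alphas = np.array([[0.0, 1.0, -1.0]])
        d = PosteriorDraws(
            draws={"alpha": alphas, "sigma": np.ones((1, 3)),
                   "b[A]": np.zeros((1, 3))},
            seed=0, n_warmup=0, acceptance=np.array([0.3]),
            province_labels=("A",),
        )
        # note: single chain is fine for likelihood evaluation
        spec = ModelSpec(y=np.array([1.0, 0.0]), X=np.zeros((2, 0)),
                         provinces=np.zeros(2, int), prior=PriorConfig(),
                         province_labels=("A",))
        ll = pointwise_loglik(d, spec)
        expected = np.array(
            [[math.log(invlogit(a)), math.log(1 - invlogit(a))]
             for a in alphas[0]]
        )
        np.testing.assert_allclose(ll, expected, rtol=1e-12)


class TestGpdFit:
    @pytest.mark.parametrize("shape,scale", [(0.1, 1.0), (0.3, 2.0), (0.7, 0.5)])
    def test_recovers_simulated_gpd(self, shape, scale):
        x = stats.genpareto.rvs(shape, scale=scale, size=4000,
                                random_state=np.random.default_rng(17))
        k, s = fit_generalized_pareto(x)
        assert k == pytest.approx(shape, abs=0.08)
        assert s == pytest.approx(scale, rel=0.15)

    def test_exponential_tail_has_near_zero_shape(self):
        x = np.random.default_rng(18).exponential(1.0, 4000)
        k, _ = fit_generalized_pareto(x)
        assert abs(k) < 0.08


class TestPsis:
    def test_constant_loglik_passthrough(self):
        ll = np.full((1000, 7), -0.35)
        res = psis_loo(ll)
        np.testing.assert_allclose(res.pointwise_elpd, -0.35)
        assert res.total_elpd == pytest.approx(-0.35 * 7)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_total_is_sum_of_pointwise(self):
        rng = np.random.default_rng(19)
        ll = -rng.exponential(1.0, size=(2000, 25))
        res = psis_loo(ll)
        assert res.total_elpd == pytest.approx(res.pointwise_elpd.sum(), rel=1e-10)

    def test_truncation_never_exceeds_raw_max(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            lr = rng.normal(0, 2, 1500)
            lw, k = smooth_importance_weights(lr)
            assert lw.max() <= lr.max() + 1e-12

    def test_smoothing_reduces_weight_variance(self):
        rng = np.random.default_rng(21)
        lr = rng.standard_t(3, 2000)  # heavy-tailed ratios
        lw, k = smooth_importance_weights(lr)
        raw = np.exp(lr - lr.max())
        sm = np.exp(lw - lr.max())
        assert sm.var() <= raw.var() + 1e-12

    def test_well_specified_model_has_small_k(self, complete_margins, prior):
        spec = build_model_spec(complete_margins, [], prior)
        draws = sample_posterior(spec, 2, 500, 2000, seed=25)
        res = psis_loo(pointwise_loglik(draws, spec))
        assert np.all(res.pareto_k < 0.7)
        assert res.n_bad_k == 0

    def test_matches_independent_psis_implementation(self):
        # arviz implements the same published smoothing recipe; agreement to
        # machine precision on both the pointwise ELPD and the tail shapes
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            import arviz
            import xarray as xr

        rng = np.random.default_rng(3)
        ll = rng.normal(-0.6, 0.4, (2000, 30)) - 0.05 * rng.exponential(1, (2000, 30))
        res = psis_loo(ll)
        lw_az, k_az = arviz.psislw(xr.DataArray(-ll.T, dims=("obs", "__sample__")))
        elpd_az = np.array(
            [logsumexp(lw_az.values[i] + ll[:, i]) for i in range(ll.shape[1])]
        )
        np.testing.assert_allclose(res.pointwise_elpd, elpd_az, atol=1e-12)
        np.testing.assert_allclose(res.pareto_k, k_az.values, atol=1e-12)

    def test_nonfinite_rejected(self):
        ll = np.zeros((500, 3))
        ll[0, 0] = np.nan
        with pytest.raises(ValidationError):
            psis_loo(ll)


class TestExactRefit:
    def test_single_observation_matches_quadrature(self):
        # n=1: elpd is the log prior-predictive probability of that outcome;
        # the oracle integrates the prior over (alpha, sigma, b) by quadrature
        prior = PriorConfig()
        spec = ModelSpec(y=np.array([1.0]), X=np.zeros((1, 0)),
                         provinces=np.zeros(1, int), prior=prior,
                         province_labels=("A",))
        res = exact_refit_loo(spec, 2, 1000, 4000, seed=3)

        # oracle: E[invlogit(alpha + b)] under the prior, via nested quadrature
        from scipy import integrate

        def inner(sigma):
            # E over alpha and b|sigma on a grid
            a = np.linspace(-6, 6, 201)
            z = np.linspace(-6, 6, 201)
            wa = stats.norm.pdf(a, prior.intercept_mean, prior.intercept_sd)
            wz = stats.norm.pdf(z)
            p = 1 / (1 + np.exp(-(a[:, None] + sigma * z[None, :])))
            return np.trapezoid(np.trapezoid(p * wz[None, :], z, axis=1) * wa, a)

        sg = np.linspace(1e-4, 10, 300)
        ws = stats.expon.pdf(sg, scale=1.0 / prior.re_sd_rate)
        prior_pred = np.trapezoid([inner(s) * w for s, w in zip(sg, ws)], sg)
        assert res.pointwise_elpd[0] == pytest.approx(math.log(prior_pred), abs=0.01)

    def test_duplicate_rows_get_equal_elpd(self, prior):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        spec = ModelSpec(y=y, X=np.zeros((4, 0)), provinces=np.zeros(4, int),
                         prior=prior, province_labels=("A",))
        res = exact_refit_loo(spec, 2, 500, 6000, seed=4)
        assert res.pointwise_elpd[0] == pytest.approx(res.pointwise_elpd[1], abs=0.02)
        assert res.pointwise_elpd[2] == pytest.approx(res.pointwise_elpd[3], abs=0.02)

    def test_guard_on_large_n(self, prior):
        spec = ModelSpec(y=np.ones(201), X=np.zeros((201, 0)),
                         provinces=np.zeros(201, int), prior=prior)
        with pytest.raises(ValidationError, match="psis_loo"):
            exact_refit_loo(spec)

    def test_agrees_with_psis_within_2se(self, prior):
        cfg = SyntheticConfig(n_respondents=40,
                              true_betas={"subspecialty": 0.8}, seed=7)
        dataset, _ = generate(cfg)
        spec = build_model_spec(dataset, ["subspecialty"], prior)
        exact = exact_refit_loo(spec, 2, 400, 800, seed=5)
        draws = sample_posterior(spec, 4, 1000, 1000, seed=5)
        psis = psis_loo(pointwise_loglik(draws, spec))
        diff = psis.pointwise_elpd - exact.pointwise_elpd
        se_diff = math.sqrt(len(diff) * diff.var())
        assert abs(psis.total_elpd - exact.total_elpd) <= 2 * se_diff


class TestCompareModels:
    def test_self_comparison_is_zero(self):
        rng = np.random.default_rng(30)
        ll = -rng.exponential(1.0, (1000, 20))
        r = psis_loo(ll)
        table = compare_models([r, r], ["m1", "m2"])
        np.testing.assert_allclose(table["delta"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["delta_se"], 0.0, atol=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(31)
        r1 = psis_loo(-rng.exponential(1.0, (800, 15)))
        r2 = psis_loo(-rng.exponential(1.2, (800, 15)))
        t1 = compare_models([r1, r2], ["a", "b"])
        t2 = compare_models([r2, r1], ["b", "a"])
        assert t1["label"].tolist() == t2["label"].tolist()
        np.testing.assert_allclose(t1["elpd"], t2["elpd"])

    def test_best_model_first_with_zero_delta(self):
        rng = np.random.default_rng(32)
        good = psis_loo(-0.2 * rng.exponential(1.0, (800, 15)))
        bad = psis_loo(-1.0 * rng.exponential(1.0, (800, 15)))
        t = compare_models([bad, good], ["bad", "good"])
        assert t.iloc[0]["label"] == "good"
        assert t.iloc[0]["delta"] == 0.0
        assert t.iloc[1]["delta"] < 0

    def test_mismatched_observation_counts_rejected(self):
        r1 = psis_loo(np.full((500, 10), -0.5))
        r2 = psis_loo(np.full((500, 11), -0.5))
        with pytest.raises(ValidationError):
            compare_models([r1, r2], ["a", "b"])
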