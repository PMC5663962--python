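"""Negative-binomial model, log posterior, sampler, and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from orphanbonds.bayes_nb import (
    McmcConfig,
    ModelSpec,
    ModelState,
    NbData,
    NbFit,
    fit,
    gelman_rubin,
    linear_predictor,
    log_posterior,
    nb_log_pmf,
    prepare_data,
)
from orphanbonds.focal_data_io import DyadObservation
from orphanbonds.population_model import PartnerCategoryFlags


def toy_data(n_dyads=10, n_focals=3, n_cov=4, seed=5):
    """Small prepared dataset with arbitrary standardized covariates."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_dyads, n_cov))
    gamma = rng.uniform(10.0, 200.0, size=n_dyads)
    y = rng.integers(0, 12, size=n_dyads).astype(float)
    fidx = np.sort(rng.integers(0, n_focals, size=n_dyads)).astype(np.int64)
    fidx[:n_focals] = np.arange(n_focals)  # every focal appears
    return NbData(y, gamma, np.log(gamma), X,
                  [f"F{i}" for i in range(n_focals)], fidx)


def toy_state(data, seed=9):
    rng = np.random.default_rng(seed)
    return ModelState(
        beta=rng.normal(0, 0.5, size=data.X.shape[1]),
        alpha=rng.normal(-1.0, 0.5, size=data.n_focals),
        mu_alpha=-1.0, tau_alpha=4.0, r=1.7,
    )


class TestLinearPredictor:
    def test_zero_coefficients_give_lambda_equal_gamma(self):
        data = toy_data()
        state = ModelState(np.zeros(4), np.zeros(data.n_focals), 0.0, 1.0, 1.0)
        assert np.allclose(linear_predictor(state, data), data.gamma)

    def test_offset_linearity_doubling_gamma_doubles_lambda(self):
        data = toy_data()
        state = toy_state(data)
        lam = linear_predictor(state, data)
        data2 = NbData(data.y, 2 * data.gamma, np.log(2 * data.gamma), data.X,
                       data.focal_ids, data.focal_index)
        assert np.allclose(linear_predictor(state, data2), 2 * lam)

    def test_log_two_intercept_doubles_exposure(self):
        data = NbData(np.array([0.0]), np.array([10.0]), np.log([10.0]),
                      np.zeros((1, 1)), ["F0"], np.array([0], dtype=np.int64))
        state = ModelState(np.zeros(1), np.array([math.log(2.0)]), 0.0, 1.0, 1.0)
        assert linear_predictor(state, data)[0] == pytest.approx(20.0)


class TestNbLogPmf:
    def test_normalizes_to_one(self):
        ys = np.arange(0, 4000)
        total = np.exp(nb_log_pmf(ys, 3.0, 1.5)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_mean_identity_by_direct_summation(self):
        ys = np.arange(0, 6000)
        p = np.exp(nb_log_pmf(ys, 5.0, 2.0))
        assert (ys * p).sum() == pytest.approx(5.0, abs=1e-8)
        # variance = lam (1 + lam / r)
        assert (ys ** 2 * p).sum() - 25.0 == pytest.approx(5.0 * (1 + 5.0 / 2.0), abs=1e-6)

    def test_poisson_limit_at_large_dispersion(self):
        # log-PMF agreement over the distribution's bulk (error ~ (y-lam)^2/2r)
        ys = np.arange(0, 16)
        nb = nb_log_pmf(ys, 5.0, 1e6)
        po = sps.poisson.logpmf(ys, 5.0)
        assert np.max(np.abs(nb - po)) < 1e-4
        # and total-variation agreement over the whole support
        all_y = np.arange(0, 2000)
        tv = 0.5 * np.abs(np.exp(nb_log_pmf(all_y, 5.0, 1e6))
                          - sps.poisson.pmf(all_y, 5.0)).sum()
        assert tv < 1e-4

    def test_matches_scipy_parameterization(self):
        ys = np.arange(0, 30)
        ours = nb_log_pmf(ys, 4.0, 2.5)
        ref = sps.nbinom.logpmf(ys, 2.5, 2.5 / (2.5 + 4.0))
        assert np.allclose(ours, ref, atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_pmf(np.array([-1]), 1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(np.array([1]), -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(np.array([1.5]), 1.0, 1.0)


class TestLogPosterior:
    @staticmethod
    def brute_force(state, data):
        """Independent direct-summation evaluation via scipy distributions."""
        lp = 0.0
        for b in state.beta:
            lp += sps.norm.logpdf(b, 0.0, math.sqrt(10.0))
        lp += sps.norm.logpdf(state.mu_alpha, 0.0, math.sqrt(10.0))
        for a in state.alpha:
            lp += sps.norm.logpdf(a, state.mu_alpha, 1.0 / math.sqrt(state.tau_alpha))
        lp += sps.uniform.logpdf(state.tau_alpha, 0.001, 99.999)
        lp += sps.uniform.logpdf(state.r, 0.0, 100.0)
        for n in range(data.n_obs):
            lam = data.gamma[n] * math.exp(
                state.alpha[data.focal_index[n]] + float(data.X[n] @ state.beta))
            lp += sps.nbinom.logpmf(int(data.y[n]), state.r,
                                    state.r / (state.r + lam))
        return lp

    def test_matches_brute_force_oracle(self):
        data = toy_data(n_dyads=10)
        for seed in range(3):
            state = toy_state(data, seed=seed)
            assert log_posterior(state, data) == pytest.approx(
                self.brute_force(state, data), abs=1e-10)

    def test_outside_uniform_support_is_minus_inf(self):
        data = toy_data()
        state = toy_state(data)
        state.tau_alpha = 200.0
        assert log_posterior(state, data) == -np.inf
        state.tau_alpha = 4.0
        state.r = 101.0
        assert log_posterior(state, data) == -np.inf

    def test_zero_dyads_gives_log_prior_only(self):
        spec = ModelSpec("orphan", "feeding")
        data = prepare_data([], spec)
        state = ModelState(np.zeros(8), np.zeros(0), 0.0, 1.0, 1.0)
        expected = (9 * sps.norm.logpdf(0.0, 0.0, math.sqrt(10.0))
                    + sps.uniform.logpdf(1.0, 0.001, 99.999)
                    + sps.uniform.logpdf(1.0, 0.0, 100.0))
        assert log_posterior(state, data) == pytest.approx(expected, abs=1e-12)


class TestSampler:
    def test_same_seed_reproduces_chains_exactly(self):
        data = toy_data(n_dyads=30, n_focals=4)
        spec = ModelSpec("orphan", "feeding")
        cfg = McmcConfig(n_chains=2, n_iter=600, seed=77)
        data.X = data.X[:, :8] if data.X.shape[1] >= 8 else np.hstack(
            [data.X, np.zeros((data.X.shape[0], 8 - data.X.shape[1]))])
        a = fit(data, spec, cfg)
        b = fit(data, spec, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_only_fit_recovers_prior_spread(self):
        """With no data the sampler must return the priors: beta sd ~ sqrt(10)."""
        spec = ModelSpec("orphan", "feeding")
        data = prepare_data([], spec)
        res = fit(data, spec, McmcConfig(n_chains=3, n_iter=6000, seed=3))
        pooled = res.pooled()
        k = res.param_names.index("beta[age]")
        assert pooled[:, k].std() == pytest.approx(math.sqrt(10.0), abs=0.35)
        assert abs(pooled[:, k].mean()) < 0.35
        # r is uniform on (0, 100) under its prior
        rk = res.param_names.index("r")
        assert pooled[:, rk].mean() == pytest.approx(50.0, abs=6.0)

    def test_thinning_reduces_kept_draws(self):
        spec = ModelSpec("orphan", "feeding")
        data = prepare_data([], spec)
        res = fit(data, spec, McmcConfig(n_chains=2, n_iter=1000, thin=5, seed=1))
        assert res.draws.shape[1] == 180  # (1000 - 100) / 5


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert gelman_rubin(np.stack([x, x, x])) == pytest.approx(1.0, abs=1e-3)

    def test_stationary_chains_below_1_01(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_separated_chains_far_above_threshold(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert gelman_rubin(chains) > 3.0

    def test_constant_identical_chains_defined_as_one(self):
        chains = np.ones((2, 100))
        assert gelman_rubin(chains) == 1.0

    def test_zero_within_variance_undefined(self):
        chains = np.stack([np.zeros(100), np.ones(100)])
        assert math.isnan(gelman_rubin(chains))

    def test_agrees_with_arviz_on_stationary_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 5000))
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(chains))
        # arviz computes rank-normalized split R-hat; near stationarity both ~ 1
        assert ours == pytest.approx(theirs, abs=0.01)


class TestSummaries:
    def _fit_from_draws(self, draws, names):
        spec = ModelSpec("orphan", "feeding")
        return NbFit(spec, McmcConfig(n_chains=draws.shape[0], n_iter=100, seed=0),
                     names, draws)

    def test_constant_samples_give_point_interval(self):
        draws = np.full((2, 50, 1), 3.25)
        s = self._fit_from_draws(draws, ["beta[age]"]).summary()
        assert s.loc["beta[age]", "median"] == 3.25
        assert s.loc["beta[age]", "ci_2.5"] == s.loc["beta[age]", "ci_97.5"] == 3.25

    def test_standard_normal_samples_give_nominal_interval(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(size=(2, 50_000, 1))
        s = self._fit_from_draws(draws, ["x"]).summary()
        assert s.loc["x", "median"] == pytest.approx(0.0, abs=0.03)
        assert s.loc["x", "ci_2.5"] == pytest.approx(-1.96, abs=0.03)
        assert s.loc["x", "ci_97.5"] == pytest.approx(1.96, abs=0.03)

    def test_summary_rows_follow_covariate_order(self):
        spec = ModelSpec("non_orphan", "resting")
        data = prepare_data([], spec)
        res = fit(data, spec, McmcConfig(n_chains=2, n_iter=200, seed=0))
        expected = [f"beta[{n}]" for n in spec.covariates] + ["mu_alpha", "tau_alpha", "r"]
        assert res.summary().index.tolist()[:len(expected)] == expected

    def test_interval_brackets_median(self):
        data = toy_data(n_dyads=40, n_focals=4, n_cov=8)
        res = fit(data, ModelSpec("orphan", "feeding"),
                  McmcConfig(n_chains=2, n_iter=800, seed=21))
        s = res.summary()
        assert (s["ci_2.5"] <= s["median"]).all()
        assert (s["median"] <= s["ci_97.5"]).all()


def test_all_zero_count_covariate_warns():
    rng = np.random.default_rng(4)
    dyads = []
    for i in range(20):
        flags = PartnerCategoryFlags(bull=(i % 4 == 0))
        cov = np.array([10.0, 5.0, 0.0, 0.0, float(flags.bull), 0.0, 0.0, 0.0])
        dyads.append(DyadObservation("F1", f"P{i}", "feeding", "orphan",
                                     0 if flags.bull else int(rng.integers(0, 3)),
                                     50.0, cov, flags))
    with pytest.warns(RuntimeWarning, match="weakly identified"):
        fit(dyads, ModelSpec("orphan", "feeding"),
            McmcConfig(n_chains=2, n_iter=300, seed=0))
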