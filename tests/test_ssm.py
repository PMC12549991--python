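"""State-space model: log-posterior oracle, structure, fitting, λ."""

import warnings

import numpy as np
import pytest
from scipy import stats

from lekdemog.mcmc import MCMCConfig
from lekdemog.ssm import (
    SSMConfig,
    SSMData,
    SSMState,
    build_ssm,
    derive_lambda,
    fit_ssm,
)
from lekdemog.synthetic import SSMTruth, gen_lek_counts


def toy_model_and_state():
    """2 leks x 3 years x 1 covariate, 2 regions, one missing count."""
    y = np.array([[10.0, 12.0, np.nan],
                  [55.0, 50.0, 61.0]])
    X = np.array([[[0.3], [-0.2], [0.1]],
                  [[-1.0], [0.4], [0.0]]])
    data = SSMData(y=y, X=X, region=np.array([0, 1]))
    model = build_ssm(data)
    state = SSMState(
        log_n=np.array([[2.35, 2.50, 2.40],
                        [4.00, 3.95, 4.10]]),
        sigma_r=np.array([0.15, 0.22]),
        alpha=np.array([0.45, 0.60]),
        beta=np.array([[0.08], [-0.05]]),
        theta=np.array([-0.09, -0.12]),
        mu_alpha=0.5,
        sigma_alpha=0.3,
        mu_beta=np.array([0.02]),
        sigma_beta=np.array([0.1]),
    )
    return model, state


def oracle_log_posterior(model, state):
    """Independent term-by-term sum of every density in the joint model,
    written with scipy.stats building blocks."""
    cfg = model.config
    data = model.data
    lp = 0.0
    for i in range(data.n_leks):
        first = np.flatnonzero(np.isfinite(data.y[i]))[0]
        lp += stats.norm.logpdf(state.log_n[i, 0],
                                np.log(data.y[i, first] + 1.0), cfg.init_sd)
        for t in range(data.n_years - 1):
            r = state.log_n[i, t + 1] - state.log_n[i, t]
            rr = data.region[i]
            mu = (state.alpha[rr]
                  + float(data.X[i, t] @ state.beta[rr])
                  + state.theta[rr] * state.log_n[i, t])
            lp += stats.norm.logpdf(r, mu, state.sigma_r[i])
        for t in range(data.n_years):
            if np.isfinite(data.y[i, t]):
                lp += stats.poisson.logpmf(int(data.y[i, t]),
                                           np.exp(state.log_n[i, t]))
    lp += stats.norm.logpdf(state.alpha, state.mu_alpha,
                            state.sigma_alpha).sum()
    lp += stats.norm.logpdf(state.beta, state.mu_beta,
                            state.sigma_beta).sum()
    lp += stats.norm.logpdf(state.mu_alpha, 0.0, cfg.hyper_mean_sd)
    lp += stats.norm.logpdf(state.mu_beta, 0.0, cfg.hyper_mean_sd).sum()
    lp += stats.halfnorm.logpdf(state.sigma_alpha,
                                scale=cfg.sd_prior_scale)
    lp += stats.halfnorm.logpdf(state.sigma_beta,
                                scale=cfg.sd_prior_scale).sum()
    lp += stats.norm.logpdf(state.theta, 0.0, cfg.theta_prior_sd).sum()
    lp += stats.halfnorm.logpdf(state.sigma_r,
                                scale=cfg.sd_prior_scale).sum()
    return float(lp)


class TestLogPosterior:
    def test_matches_term_by_term_oracle(self):
        model, state = toy_model_and_state()
        assert model.log_posterior(state) == pytest.approx(
            oracle_log_posterior(model, state), rel=1e-12)

    def test_oracle_agreement_at_random_points(self):
        model, state = toy_model_and_state()
        rng = np.random.default_rng(14)
        for _ in range(20):
            state.log_n = state.log_n + rng.normal(scale=0.3,
                                                   size=state.log_n.shape)
            state.theta = rng.normal(-0.1, 0.05, size=2)
            state.sigma_r = rng.uniform(0.05, 0.5, size=2)
            assert model.log_posterior(state) == pytest.approx(
                oracle_log_posterior(model, state), rel=1e-10)

    def test_drift_reduces_to_alpha_without_covariates_and_density(self):
        model, state = toy_model_and_state()
        state.beta = np.zeros((2, 1))
        state.theta = np.zeros(2)
        mu = model.drift(state)
        expected = state.alpha[model.data.region][:, None] * np.ones((2, 2))
        np.testing.assert_allclose(mu, expected)

    def test_lek_permutation_invariance(self):
        model, state = toy_model_and_state()
        lp = model.log_posterior(state)
        perm = [1, 0]
        data_p = SSMData(y=model.data.y[perm], X=model.data.X[perm],
                         region=model.data.region[perm])
        model_p = build_ssm(data_p)
        state_p = SSMState(
            log_n=state.log_n[perm], sigma_r=state.sigma_r[perm],
            alpha=state.alpha, beta=state.beta, theta=state.theta,
            mu_alpha=state.mu_alpha, sigma_alpha=state.sigma_alpha,
            mu_beta=state.mu_beta, sigma_beta=state.sigma_beta)
        assert model_p.log_posterior(state_p) == pytest.approx(lp, rel=1e-12)

    def test_missing_covariate_for_observed_year_rejected(self):
        y = np.array([[5.0, 6.0, 7.0]])
        X = np.array([[[0.1], [np.nan], [0.2]]])
        with pytest.raises(ValueError, match="covariate row missing"):
            SSMData(y=y, X=X, region=np.array([0]))

    def test_single_region_collapses_with_warning(self):
        y = np.array([[5.0, 6.0, 7.0]])
        X = np.zeros((1, 3, 0))
        data = SSMData(y=y, X=X, region=np.array([0]))
        with pytest.warns(UserWarning, match="single region"):
            model = build_ssm(data)
        assert not model.hierarchical


@pytest.fixture(scope="module")
def small_fit(small_lek_sim):
    model = build_ssm(small_lek_sim.data)
    cfg = MCMCConfig(iterations=6000, burn_in=2500, thin=2, chains=4,
                     seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_ssm(model, cfg)


class TestFit:
    def test_draw_shapes_consistent(self, small_fit, small_lek_sim):
        n, T = small_lek_sim.data.y.shape
        chains, kept = small_fit.draws["alpha"].shape[:2]
        assert small_fit.draws["theta"].shape == (chains, kept, 2)
        assert small_fit.draws["sigma_r"].shape == (chains, kept, n)
        assert small_fit.latent_log_n.shape[2:] == (n, T)

    def test_theta_recovered_within_two_posterior_sd(self, small_fit,
                                                     small_lek_sim):
        s = small_fit.summarize(force=True).set_index("parameter")
        for rr in range(2):
            row = s.loc[f"theta[{rr}]"]
            assert abs(row["mean"] - small_lek_sim.truth.theta) < \
                2.5 * row["sd"]

    def test_posterior_predictive_mean_matches_observed(self, small_fit,
                                                        small_lek_sim):
        obs = small_lek_sim.data.y
        mask = np.isfinite(obs)
        pred = np.exp(small_fit.latent_log_n).mean(axis=(0, 1))
        rel = abs(pred[mask].mean() - obs[mask].mean()) / obs[mask].mean()
        assert rel < 0.05

    def test_random_walk_alpha_matches_log_diff_mean(self):
        # with theta = 0 and no covariates the model is a stochastic
        # random walk with drift: the posterior of alpha tracks the mean
        # observed log-count difference (closed-form oracle on dense data)
        truth = SSMTruth(n_regions=1, n_leks=10, n_years=12, n_covariates=0,
                         mu_beta=(), sigma_beta=(), mu_alpha=0.04,
                         sigma_alpha=0.0, theta=0.0, process_sd=0.05,
                         init_log_n_mean=5.0, missing_fraction=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = gen_lek_counts(truth, seed=33)
            model = build_ssm(sim.data)
            cfg = MCMCConfig(iterations=4000, burn_in=2000, thin=2,
                             chains=2, seed=34)
            fit = fit_ssm(model, cfg)
        diffs = np.diff(np.log(sim.data.y), axis=1)
        oracle = float(np.nanmean(diffs))
        row = fit.summarize(force=True).set_index("parameter").loc["alpha[0]"]
        assert abs(row["mean"] - oracle) < max(3 * row["sd"], 0.02)


class TestDeriveLambda:
    def test_zero_growth_gives_lambda_one(self, small_lek_sim):
        model = build_ssm(small_lek_sim.data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ssm(model, MCMCConfig(iterations=200, burn_in=100,
                                            thin=1, chains=2, seed=3))
        fit.latent_log_n = np.full_like(fit.latent_log_n, 4.0)
        lam = derive_lambda(fit, scope="global")
        np.testing.assert_allclose(lam["lambda_draws"], 1.0)

    def test_percent_effect_inverts_growth_coefficient(self, small_lek_sim):
        model = build_ssm(small_lek_sim.data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ssm(model, MCMCConfig(iterations=200, burn_in=100,
                                            thin=1, chains=2, seed=3))
        fit.draws["mu_beta"] = np.full_like(fit.draws["mu_beta"], 0.00608)
        lam = derive_lambda(fit, scope="global")
        # a +1-unit covariate effect of 0.00608 on r is a 0.61% effect on λ
        np.testing.assert_allclose(lam["percent_effect_draws"], 0.6099,
                                   rtol=1e-3)

    def test_scopes_are_consistent(self, small_lek_sim):
        model = build_ssm(small_lek_sim.data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_ssm(model, MCMCConfig(iterations=400, burn_in=200,
                                            thin=1, chains=2, seed=5))
        by_lek = derive_lambda(fit, "lek")["lambda_draws"]
        overall = derive_lambda(fit, "global")["lambda_draws"]
        np.testing.assert_allclose(by_lek.mean(axis=-1), overall, rtol=1e-10)
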