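"""Hierarchical Gompertz state-space model for lek-count population dynamics.

Process model, per lek ``i`` and year ``t``::

    log N[i, t+1] = log N[i, t] + r[i, t]
    r[i, t] ~ Normal(mu_r[i, t], sigma_r[i]^2)
    mu_r[i, t] = alpha[R(i)] + X[i, t]' beta[R(i)] + theta[R(i)] * log N[i, t]

with Poisson observation ``y[i, t] ~ Poisson(N[i, t])`` on the natural
scale.  ``theta < 0`` gives Gompertz density dependence (stationary
log-abundance dynamics); the density term acts on the abundance at the start
of the t -> t+1 transition.  Region-level intercepts and coefficients are
hierarchical::

    alpha[R] ~ Normal(mu, sigma^2)
    beta[k, R] ~ Normal(mu_beta[k], sigma_beta[k]^2)

with vague Normal(0, 5^2) hyperpriors on the means and half-Normal(1) priors
on all standard deviations; ``theta[R] ~ Normal(0, 5^2)`` independent.

Fitting is by blocked Metropolis-within-Gibbs: red-black single-site
Metropolis updates of the latent log-abundances (conditionally independent
given the opposite color), conjugate multivariate-normal Gibbs draws of each
region's ``(alpha, beta, theta)`` block, conjugate draws of the
hypermeans, and log-scale random-walk Metropolis for every standard
deviation.  Proposal scales adapt during burn-in only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diagnostics import summarize_draws, converged
from .mcmc import MCMCConfig

__all__ = [
    "SSMConfig",
    "SSMData",
    "SSMModel",
    "SSMState",
    "SSMFit",
    "build_ssm",
    "fit_ssm",
    "derive_lambda",
    "lek_frame_to_arrays",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SSMConfig:
    """Structural and prior choices for the population SSM.

    ``density_on_log`` selects theta * log(N) (Gompertz, default) versus
    theta * N inside the drift; ``center_density`` subtracts the mean
    observed log-count so theta and alpha decorrelate.
    """

    density_on_log: bool = True
    center_density: bool = False
    hyper_mean_sd: float = 5.0
    sd_prior_scale: float = 1.0
    theta_prior_sd: float = 5.0
    init_sd: float = 1.0
    latent_accept_target: float = 0.44
    latent_extra_thin: int = 5


@dataclass
class SSMData:
    """Aligned arrays for the SSM: counts, covariates, region labels."""

    y: np.ndarray        # (n_leks, T); NaN marks missing counts
    X: np.ndarray        # (n_leks, T, K); K may be 0
    region: np.ndarray   # (n_leks,) integer region index
    lek_ids: tuple = ()
    years: tuple = ()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.region = np.asarray(self.region, dtype=int)
        n, T = self.y.shape
        if self.X.shape[:2] != (n, T):
            raise ValueError("X must be (n_leks, n_years, K)")
        if self.region.shape != (n,):
            raise ValueError("region must have one entry per lek")
        obs = np.isfinite(self.y)
        if obs.any() and self.y[obs].min() < 0:
            raise ValueError("counts must be non-negative")
        bad = obs[:, :-1] & ~np.isfinite(self.X[:, :-1]).all(axis=2)
        if bad.any():
            i, t = np.argwhere(bad)[0]
            raise ValueError(
                f"covariate row missing for observed lek-year (lek index {i}, "
                f"year index {t})"
            )

    @property
    def n_leks(self) -> int:
        return self.y.shape[0]

    @property
    def n_years(self) -> int:
        return self.y.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[2]

    @property
    def n_regions(self) -> int:
        return int(self.region.max()) + 1


def lek_frame_to_arrays(frame: pd.DataFrame,
                        covariates: Sequence[str] = ()) -> SSMData:
    """Pivot a validated long-format lek table into SSM arrays.

    ``frame`` needs columns lek_id, region_id, year, count plus any
    covariate columns; years are filled to the global contiguous range with
    missing markers.
    """
    years = np.arange(frame["year"].min(), frame["year"].max() + 1)
    lek_ids = sorted(frame["lek_id"].unique())
    n, T = len(lek_ids), len(years)
    y = np.full((n, T), np.nan)
    X = np.zeros((n, T, len(covariates)))
    region_of = frame.groupby("lek_id")["region_id"].first()
    regions = sorted(region_of.unique())
    region_index = {r: j for j, r in enumerate(regions)}
    lek_index = {l: j for j, l in enumerate(lek_ids)}
    year_index = {int(yr): j for j, yr in enumerate(years)}
    region = np.array([region_index[region_of[l]] for l in lek_ids])
    for row in frame.itertuples(index=False):
        i = lek_index[row.lek_id]
        t = year_index[int(row.year)]
        y[i, t] = row.count
        for k, c in enumerate(covariates):
            X[i, t, k] = getattr(row, c)
    return SSMData(y=y, X=X, region=region,
                   lek_ids=tuple(lek_ids), years=tuple(int(v) for v in years))


@dataclass
class SSMState:
    """One point in the SSM parameter space (used by the log-posterior
    oracle surface and as the sampler's mutable state)."""

    log_n: np.ndarray       # (n_leks, T)
    sigma_r: np.ndarray     # (n_leks,)
    alpha: np.ndarray       # (R,)
    beta: np.ndarray        # (R, K)
    theta: np.ndarray       # (R,)
    mu_alpha: float
    sigma_alpha: float
    mu_beta: np.ndarray     # (K,)
    sigma_beta: np.ndarray  # (K,)


class SSMModel:
    """A built SSM: data plus configuration, exposing the exact joint
    log-posterior (the correctness surface checked against a term-by-term
    oracle in the tests)."""

    def __init__(self, data: SSMData, config: SSMConfig | None = None) -> None:
        self.data = data
        self.config = config or SSMConfig()
        self.hierarchical = data.n_regions >= 2
        if not self.hierarchical:
            warnings.warn(
                "single region: hierarchical priors collapse to vague "
                "non-hierarchical priors", stacklevel=2,
            )
        self.obs_mask = np.isfinite(data.y)
        if not self.obs_mask.any(axis=1).all():
            raise ValueError("every lek needs at least one observed count")
        self.y_filled = np.where(self.obs_mask, data.y, 0.0)
        self._gammaln_y = np.where(self.obs_mask, gammaln(self.y_filled + 1.0), 0.0)
        # anchor for the latent initial condition: first observed count
        first_idx = np.argmax(self.obs_mask, axis=1)
        first_count = data.y[np.arange(data.n_leks), first_idx]
        self.m_init = np.log(first_count + 1.0)
        if self.config.center_density:
            self.dens_center = float(
                np.log(data.y[self.obs_mask] + 1.0).mean())
        else:
            self.dens_center = 0.0

    def density_term(self, log_n: np.ndarray) -> np.ndarray:
        """The density covariate entering the drift (log N by default)."""
        if self.config.density_on_log:
            return log_n - self.dens_center
        return np.exp(log_n) - self.dens_center

    def drift(self, state: SSMState) -> np.ndarray:
        """mu_r[i, t] for transitions t -> t+1, shape (n_leks, T-1)."""
        reg = self.data.region
        c = state.alpha[reg][:, None] + np.einsum(
            "itk,ik->it", self.data.X[:, :-1, :], state.beta[reg])
        return c + state.theta[reg][:, None] * self.density_term(
            state.log_n[:, :-1])

    def log_posterior(self, state: SSMState) -> float:
        """Exact joint log-posterior (all normalizing constants included)."""
        cfg = self.config
        log_n = state.log_n
        n, T = log_n.shape
        lp = 0.0
        # latent initial condition
        lp += float(np.sum(_norm_logpdf(log_n[:, 0], self.m_init, cfg.init_sd)))
        # transitions
        r = np.diff(log_n, axis=1)
        mu = self.drift(state)
        lp += float(np.sum(_norm_logpdf(r, mu, state.sigma_r[:, None])))
        # Poisson observation
        lam = np.exp(log_n)
        obs = self.obs_mask
        lp += float(np.sum(
            (self.y_filled * log_n - lam - self._gammaln_y)[obs]))
        # region-level priors
        if self.hierarchical:
            lp += float(np.sum(_norm_logpdf(
                state.alpha, state.mu_alpha, state.sigma_alpha)))
            lp += float(np.sum(_norm_logpdf(
                state.beta, state.mu_beta[None, :], state.sigma_beta[None, :])))
            lp += float(_norm_logpdf(
                np.asarray(state.mu_alpha), 0.0, cfg.hyper_mean_sd))
            lp += float(np.sum(_norm_logpdf(state.mu_beta, 0.0, cfg.hyper_mean_sd)))
            lp += float(_halfnorm_logpdf(
                np.asarray(state.sigma_alpha), cfg.sd_prior_scale))
            lp += float(np.sum(_halfnorm_logpdf(state.sigma_beta, cfg.sd_prior_scale)))
        else:
            lp += float(np.sum(_norm_logpdf(state.alpha, 0.0, cfg.hyper_mean_sd)))
            lp += float(np.sum(_norm_logpdf(state.beta, 0.0, cfg.hyper_mean_sd)))
        lp += float(np.sum(_norm_logpdf(state.theta, 0.0, cfg.theta_prior_sd)))
        lp += float(np.sum(_halfnorm_logpdf(state.sigma_r, cfg.sd_prior_scale)))
        return lp


def _norm_logpdf(x, mean, sd):
    sd = np.asarray(sd, dtype=float)
    z = (np.asarray(x, dtype=float) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI


def _halfnorm_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        np.log(2.0) - 0.5 * _LOG2PI - np.log(scale)
        - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def build_ssm(data: SSMData | pd.DataFrame, config: SSMConfig | None = None,
              covariates: Sequence[str] = ()) -> SSMModel:
    """Build the SSM from arrays or a long-format lek frame."""
    if isinstance(data, pd.DataFrame):
        data = lek_frame_to_arrays(data, covariates)
    return SSMModel(data, config)


@dataclass
class SSMFit:
    """Posterior draws of a fitted SSM.

    Top-level parameter draws have shape ``(chains, n_kept, ...)``; latent
    log-abundance draws are extra-thinned (``latent_thin``) to keep memory
    bounded.  ``summarize`` refuses to produce the reporting table while any
    R-hat is >= 1.1 unless forced, matching the convergence gate used in
    the field.
    """

    model: SSMModel
    draws: dict
    latent_log_n: np.ndarray   # (chains, n_latent_kept, n_leks, T)
    latent_thin: int
    converged: bool
    _summary: pd.DataFrame

    def summarize(self, force: bool = False) -> pd.DataFrame:
        if not self.converged and not force:
            raise RuntimeError(
                "chains not converged (R-hat >= 1.1); pass force=True to "
                "summarize anyway"
            )
        return self._summary

    @property
    def r_draws(self) -> np.ndarray:
        """Growth-rate draws r[i, t] from the latent log-abundances."""
        return np.diff(self.latent_log_n, axis=-1)


def _init_latents(model: SSMModel) -> np.ndarray:
    """Fill missing log-counts by per-lek linear interpolation."""
    y = model.data.y
    n, T = y.shape
    out = np.empty((n, T))
    tt = np.arange(T)
    for i in range(n):
        obs = np.isfinite(y[i])
        vals = np.log(y[i, obs] + 1.0)
        out[i] = np.interp(tt, tt[obs], vals)
    return out


def fit_ssm(model: SSMModel, config: MCMCConfig | None = None) -> SSMFit:
    """Fit the SSM by blocked Metropolis-within-Gibbs MCMC."""
    cfg = config or MCMCConfig(iterations=10000, burn_in=4000, thin=3, chains=4)
    data, scfg = model.data, model.config
    n, T, K = data.n_leks, data.n_years, data.n_covariates
    R = data.n_regions
    reg = data.region
    rng_master = np.random.default_rng(cfg.seed)
    chain_seeds = rng_master.integers(0, 2**31 - 1, size=cfg.chains)

    n_kept = cfg.n_kept
    lat_thin = scfg.latent_extra_thin
    n_lat = (n_kept + lat_thin - 1) // lat_thin

    out = {
        "alpha": np.empty((cfg.chains, n_kept, R)),
        "beta": np.empty((cfg.chains, n_kept, R, K)),
        "theta": np.empty((cfg.chains, n_kept, R)),
        "sigma_r": np.empty((cfg.chains, n_kept, n)),
        "mu_alpha": np.empty((cfg.chains, n_kept)),
        "sigma_alpha": np.empty((cfg.chains, n_kept)),
        "mu_beta": np.empty((cfg.chains, n_kept, K)),
        "sigma_beta": np.empty((cfg.chains, n_kept, K)),
    }
    latent = np.empty((cfg.chains, n_lat, n, T))

    even_ts = np.arange(0, T, 2)
    odd_ts = np.arange(1, T, 2)
    obs_mask = model.obs_mask
    y_filled = model.y_filled
    Xtr = data.X[:, :-1, :]        # covariates entering transitions

    prior_prec = np.empty(K + 2)
    hyper_var0 = scfg.hyper_mean_sd ** 2

    for c in range(cfg.chains):
        rng = np.random.default_rng(chain_seeds[c])
        logn = _init_latents(model) + rng.normal(scale=0.05, size=(n, T))
        sigma_r = np.full(n, 0.2)
        alpha = rng.normal(scale=0.05, size=R)
        beta = rng.normal(scale=0.05, size=(R, K))
        theta = np.full(R, -0.02) + rng.normal(scale=0.01, size=R)
        mu_alpha, sigma_alpha = 0.0, 0.5
        mu_beta = np.zeros(K)
        sigma_beta = np.full(K, 0.5)

        lat_scale = np.full((n, T), 0.2)
        sig_scale = np.full(n, 0.3)
        hyp_scale = 0.3

        theta_lek = theta[reg]
        drift_c = alpha[reg][:, None] + np.einsum("itk,ik->it", Xtr, beta[reg])

        kept = 0
        lat_kept = 0
        for it in range(cfg.iterations):
            adapting = it < cfg.burn_in
            gamma = 1.0 / (1 + it) ** 0.6 if adapting else 0.0

            # --- latent updates, red-black over year parity -----------------
            for ts in (even_ts, odd_ts):
                cur = logn[:, ts]
                prop = cur + lat_scale[:, ts] * rng.standard_normal(cur.shape)
                d_new = _local_logdens(model, ts, prop, logn, drift_c,
                                       theta_lek, sigma_r)
                d_old = _local_logdens(model, ts, cur, logn, drift_c,
                                       theta_lek, sigma_r)
                acc = np.log(rng.random(cur.shape)) < d_new - d_old
                logn[:, ts] = np.where(acc, prop, cur)
                if adapting:
                    lat_scale[:, ts] *= np.exp(
                        gamma * (acc - scfg.latent_accept_target))

            dens = model.density_term(logn[:, :-1])
            r_obs = np.diff(logn, axis=1)

            # --- per-lek process sd (log-scale MH) --------------------------
            mu = drift_c + theta_lek[:, None] * dens
            resid2 = np.sum((r_obs - mu) ** 2, axis=1)
            prop_sig = sigma_r * np.exp(sig_scale * rng.standard_normal(n))
            def _sig_lp(s):
                return (-(T - 1) * np.log(s) - 0.5 * resid2 / s**2
                        - 0.5 * (s / scfg.sd_prior_scale) ** 2 + np.log(s))
            acc = np.log(rng.random(n)) < _sig_lp(prop_sig) - _sig_lp(sigma_r)
            sigma_r = np.where(acc, prop_sig, sigma_r)
            if adapting:
                sig_scale *= np.exp(gamma * (acc - 0.44))

            # --- conjugate Gibbs for each region's (alpha, beta, theta) -----
            prior_prec[0] = (1.0 / sigma_alpha**2 if model.hierarchical
                             else 1.0 / hyper_var0)
            if K:
                prior_prec[1:K + 1] = (1.0 / sigma_beta**2 if model.hierarchical
                                       else 1.0 / hyper_var0)
            prior_prec[K + 1] = 1.0 / scfg.theta_prior_sd**2
            prior_mean = np.concatenate((
                [mu_alpha if model.hierarchical else 0.0],
                mu_beta if model.hierarchical else np.zeros(K),
                [0.0]))
            w = 1.0 / sigma_r**2
            for rr in range(R):
                leks = np.flatnonzero(reg == rr)
                Z = np.concatenate(
                    [np.ones((leks.size, T - 1, 1)),
                     Xtr[leks],
                     dens[leks][:, :, None]], axis=2).reshape(-1, K + 2)
                wts = np.repeat(w[leks], T - 1)
                resp = r_obs[leks].ravel()
                A = np.diag(prior_prec) + (Z * wts[:, None]).T @ Z
                b = prior_prec * prior_mean + (Z * wts[:, None]).T @ resp
                L = np.linalg.cholesky(A)
                mean_vec = np.linalg.solve(A, b)
                draw = mean_vec + np.linalg.solve(
                    L.T, rng.standard_normal(K + 2))
                alpha[rr] = draw[0]
                beta[rr] = draw[1:K + 1]
                theta[rr] = draw[K + 1]
            theta_lek = theta[reg]
            drift_c = alpha[reg][:, None] + np.einsum(
                "itk,ik->it", Xtr, beta[reg])

            # --- hyperparameters -------------------------------------------
            if model.hierarchical:
                v = 1.0 / (R / sigma_alpha**2 + 1.0 / hyper_var0)
                mu_alpha = rng.normal(v * alpha.sum() / sigma_alpha**2,
                                      np.sqrt(v))
                if K:
                    vb = 1.0 / (R / sigma_beta**2 + 1.0 / hyper_var0)
                    mu_beta = rng.normal(
                        vb * beta.sum(axis=0) / sigma_beta**2, np.sqrt(vb))

                def _sd_lp(s, dev2, m):
                    return (-m * np.log(s) - 0.5 * dev2 / s**2
                            - 0.5 * (s / scfg.sd_prior_scale) ** 2 + np.log(s))

                dev2 = np.sum((alpha - mu_alpha) ** 2)
                prop = sigma_alpha * np.exp(hyp_scale * rng.standard_normal())
                if np.log(rng.random()) < (_sd_lp(prop, dev2, R)
                                           - _sd_lp(sigma_alpha, dev2, R)):
                    sigma_alpha = prop
                if K:
                    dev2b = np.sum((beta - mu_beta) ** 2, axis=0)
                    propb = sigma_beta * np.exp(
                        hyp_scale * rng.standard_normal(K))
                    accb = (np.log(rng.random(K))
                            < _sd_lp(propb, dev2b, R) - _sd_lp(sigma_beta, dev2b, R))
                    sigma_beta = np.where(accb, propb, sigma_beta)

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                out["alpha"][c, kept] = alpha
                out["beta"][c, kept] = beta
                out["theta"][c, kept] = theta
                out["sigma_r"][c, kept] = sigma_r
                out["mu_alpha"][c, kept] = mu_alpha
                out["sigma_alpha"][c, kept] = sigma_alpha
                out["mu_beta"][c, kept] = mu_beta
                out["sigma_beta"][c, kept] = sigma_beta
                if kept % lat_thin == 0:
                    latent[c, lat_kept] = logn
                    lat_kept += 1
                kept += 1

    top = {
        "alpha": out["alpha"], "theta": out["theta"],
        "mu_alpha": out["mu_alpha"],
    }
    if K:
        top["mu_beta"] = out["mu_beta"]
    if model.hierarchical:
        top["sigma_alpha"] = out["sigma_alpha"]
        if K:
            top["sigma_beta"] = out["sigma_beta"]
    if K:
        top["beta"] = out["beta"]
    summary = summarize_draws(top)
    ok = converged(summary)
    if not ok:
        warnings.warn("SSM chains not converged (some R-hat >= 1.1)",
                      stacklevel=2)
    return SSMFit(model=model, draws=out, latent_log_n=latent[:, :lat_kept],
                  latent_thin=lat_thin, converged=ok, _summary=summary)


def _local_logdens(model: SSMModel, ts: np.ndarray, V: np.ndarray,
                   logn: np.ndarray, drift_c: np.ndarray,
                   theta_lek: np.ndarray, sigma_r: np.ndarray) -> np.ndarray:
    """Site-local unnormalized log-density of latent values ``V`` at year
    columns ``ts`` (everything else held fixed)."""
    n, T = logn.shape
    out = np.zeros_like(V)
    if ts[0] == 0:
        out[:, 0] += -0.5 * ((V[:, 0] - model.m_init)
                             / model.config.init_sd) ** 2
    obs = model.obs_mask[:, ts]
    out += np.where(obs, model.y_filled[:, ts] * V - np.exp(V), 0.0)
    inv2 = 1.0 / (2.0 * sigma_r**2)
    left = ts > 0
    if left.any():
        tl = ts[left]
        prev = logn[:, tl - 1]
        mu = drift_c[:, tl - 1] + theta_lek[:, None] * model.density_term(prev)
        out[:, left] += -((V[:, left] - prev) - mu) ** 2 * inv2[:, None]
    right = ts < T - 1
    if right.any():
        tr = ts[right]
        nxt = logn[:, tr + 1]
        mu = drift_c[:, tr] + theta_lek[:, None] * model.density_term(V[:, right])
        out[:, right] += -((nxt - V[:, right]) - mu) ** 2 * inv2[:, None]
    return out


def derive_lambda(fit: SSMFit, scope: str = "global") -> dict:
    """Finite rate of change λ = exp(r) summarized at the requested scope.

    ``scope`` is ``"lek"``, ``"region"``, or ``"global"``.  Also returns the
    marginal percent effect on λ of a unit covariate change,
    ``100 * (exp(mu_beta_k) - 1)``, per covariate hypermean.
    """
    r = fit.r_draws                    # (chains, draws, n_leks, T-1)
    lam = np.exp(r)
    if scope == "global":
        lam_scope = lam.mean(axis=(2, 3))
    elif scope == "lek":
        lam_scope = lam.mean(axis=3)
    elif scope == "region":
        reg = fit.model.data.region
        R = fit.model.data.n_regions
        lam_scope = np.stack(
            [lam[:, :, reg == rr, :].mean(axis=(2, 3)) for rr in range(R)],
            axis=-1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    result = {"lambda_draws": lam_scope,
              "lambda_summary": summarize_draws({"lambda": lam_scope})}
    if fit.model.data.n_covariates:
        mb = fit.draws["mu_beta"]      # (chains, n, K)
        pct = 100.0 * (np.exp(mb) - 1.0)
        result["percent_effect_draws"] = pct
        result["percent_effect_summary"] = summarize_draws(
            {"percent_effect": pct})
    return result


def posterior_predictive_chisq(fit: SSMFit, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square discrepancy per latent draw for observed vs replicated
    counts (inputs to the posterior-predictive p-value)."""
    from .diagnostics import chi_square_discrepancy

    rng = np.random.default_rng(seed)
    obs = fit.model.obs_mask
    y = fit.model.data.y[obs]
    lat = fit.latent_log_n.reshape(-1, *fit.latent_log_n.shape[2:])
    t_obs = np.empty(lat.shape[0])
    t_rep = np.empty(lat.shape[0])
    for i, ln in enumerate(lat):
        mu = np.exp(ln[obs])
        y_rep = rng.poisson(mu)
        t_obs[i] = chi_square_discrepancy(y, mu)
        t_rep[i] = chi_square_discrepancy(y_rep, mu)
    return t_obs, t_rep
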