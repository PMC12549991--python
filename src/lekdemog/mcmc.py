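"""General-purpose adaptive random-walk Metropolis sampler.

Used by the logistic-exposure survival models and the variable-selection
stage, whose posteriors are low-dimensional (< ~25 coefficients).  The
population state-space model has its own blocked Metropolis-within-Gibbs
sampler in :mod:`lekdemog.ssm`; this module provides the shared MCMC
configuration object for both.

The proposal adapts during burn-in only (Haario-style empirical covariance
plus Robbins-Monro scaling toward a target acceptance rate); adaptation is
frozen afterwards, so post-burn-in draws come from a valid Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = ["MCMCConfig", "adaptive_metropolis", "FIELD_PROFILE", "FIELD_PROFILE_SELECTION_SSM"]


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC run settings.

    ``iterations`` is the total per-chain iteration count; the first
    ``burn_in`` are discarded and the remainder thinned by ``thin``.  At
    least two chains are required so that R-hat is defined.
    """

    iterations: int = 12000
    burn_in: int = 6000
    thin: int = 4
    chains: int = 4
    seed: int = 0
    target_accept: float = 0.25
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required (R-hat)")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=int(seed))


#: Field-scale sampler settings for the survival models
#: (50,000 iterations, 25,000 burn-in, thin 10).
FIELD_PROFILE = MCMCConfig(iterations=50_000, burn_in=25_000, thin=10, chains=3)

#: The longer field-scale profile for the variable-selection population SSM
#: (100,000 iterations, 50,000 burn-in, thin 20).
FIELD_PROFILE_SELECTION_SSM = MCMCConfig(
    iterations=100_000, burn_in=50_000, thin=20, chains=3
)


def adaptive_metropolis(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: MCMCConfig,
    jitter: float = 0.5,
    mh_mask: np.ndarray | None = None,
    gibbs: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    init_cov: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a log-posterior with per-chain adaptive random-walk Metropolis.

    Parameters
    ----------
    log_post
        Unnormalized log-posterior over a flat parameter vector; must return
        ``-inf`` (not raise) outside the support.
    x0
        Starting point, shape ``(d,)``; each chain starts from ``x0`` plus
        Gaussian jitter of scale ``jitter * init_scale``.
    config
        Run settings; ``config.seed`` seeds all chains reproducibly.
    mh_mask
        Boolean mask over dimensions moved by the random-walk proposal;
        the remaining coordinates must be handled by ``gibbs``.
    gibbs
        Optional exact conditional update applied once per iteration after
        the MH step; receives the full vector and the chain RNG and returns
        the updated vector (used e.g. for conjugate shrinkage-rate draws).

    Returns
    -------
    draws : ndarray, shape (chains, n_kept, d)
    accept_rate : ndarray, shape (chains,)
        Post-burn-in acceptance rates.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    if mh_mask is None:
        mh_mask = np.ones(d, dtype=bool)
    else:
        mh_mask = np.asarray(mh_mask, dtype=bool)
        if not mh_mask.all() and gibbs is None:
            raise ValueError("masked-out coordinates need a gibbs update")
    dm = int(mh_mask.sum())
    rng = np.random.default_rng(config.seed)
    draws = np.empty((config.chains, config.n_kept, d))
    accept_rates = np.empty(config.chains)

    for c in range(config.chains):
        x = x0.copy()
        x[mh_mask] += rng.normal(scale=jitter * config.init_scale, size=dm)
        lp = float(log_post(x))
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            x = x0.copy()
            x[mh_mask] += rng.normal(scale=jitter * config.init_scale, size=dm)
            lp = float(log_post(x))
            tries += 1
        if not np.isfinite(lp):
            raise RuntimeError("could not find a finite starting point")

        log_s = np.log(config.init_scale)
        mean = x[mh_mask].copy()
        cov = np.eye(dm) if init_cov is None else np.asarray(init_cov, float).copy()
        chol = np.linalg.cholesky(cov + 1e-6 * np.eye(dm))
        kept = 0
        accepted_post = 0
        post_iters = 0
        for it in range(config.iterations):
            prop = x.copy()
            prop[mh_mask] += np.exp(log_s) * (chol @ rng.standard_normal(dm))
            lp_prop = float(log_post(prop))
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
            if gibbs is not None:
                x = gibbs(x, rng)
                lp = float(log_post(x))
            if it < config.burn_in:
                # Haario adaptation: recursive empirical moments + RM scaling.
                k = it + 1
                gamma = 1.0 / (k + 10) ** 0.6
                delta = x[mh_mask] - mean
                mean = mean + delta / (k + 1)
                cov = cov + gamma * (np.outer(delta, delta) - cov)
                log_s += gamma * ((1.0 if accept else 0.0) - config.target_accept)
                if k % 50 == 0:
                    chol = np.linalg.cholesky(cov + 1e-6 * np.eye(dm))
            else:
                post_iters += 1
                accepted_post += int(accept)
                if (it - config.burn_in) % config.thin == 0:
                    draws[c, kept] = x
                    kept += 1
        accept_rates[c] = accepted_post / max(post_iters, 1)
    return draws, accept_rates
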