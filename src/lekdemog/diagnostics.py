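"""Convergence and posterior-reporting statistics.

Implements the reporting contract used throughout the package: Gelman-Rubin
potential scale reduction (R-hat), probability of direction (pd), equal-tailed
credible intervals, posterior-predictive (Bayesian) p-values, and tabular
posterior summaries with the column set
``mean, sd, q2.5, q50, q97.5, rhat, pd``.

Conventions
-----------
* R-hat uses the classic two-stage (non-split) formula by default; a
  split-chain variant is available via ``split=True``.  Chains converged when
  R-hat < 1.1.
* pd is the fraction of draws sharing the sign of the posterior *median*
  (primary convention); a mean-referenced variant is available because some
  reporting styles define it against the mean.  Draws exactly at zero are
  counted with the reference sign.
* Credible intervals are equal-tailed draw quantiles with linear
  interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "gelman_rubin",
    "prob_direction",
    "credible_interval",
    "evidence_category",
    "bayesian_pvalue",
    "chi_square_discrepancy",
    "bernoulli_deviance",
    "summarize_draws",
    "SUMMARY_COLUMNS",
]

#: Column order of every posterior-summary table written by this package.
SUMMARY_COLUMNS = ["parameter", "mean", "sd", "q2.5", "q50", "q97.5", "rhat", "pd"]

RHAT_THRESHOLD = 1.1


def _as_chains(chains: np.ndarray) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a (chains, draws) array, got shape {arr.shape}")
    return arr


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor from parallel chains.

    Parameters
    ----------
    chains
        Array of shape ``(m, n)``: ``m`` chains of ``n`` draws each.
    split
        If True, each chain is split in half first (2m half-chains), which
        also detects within-chain non-stationarity.

    Returns
    -------
    float
        R-hat; ``nan`` when the within-chain variance is zero (degenerate
        draws make the statistic undefined).
    """
    arr = _as_chains(chains)
    m, n = arr.shape
    if m < 2:
        raise ValueError("R-hat requires at least 2 chains")
    if n < 10:
        raise ValueError("R-hat requires chains of length >= 10")
    if split:
        half = n // 2
        arr = np.concatenate([arr[:, :half], arr[:, n - half:]], axis=0)
        m, n = arr.shape
    within = arr.var(axis=1, ddof=1).mean()
    if within == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined", stacklevel=2)
        return float("nan")
    between_over_n = arr.mean(axis=1).var(ddof=1)  # B/n
    var_plus = (n - 1) / n * within + between_over_n
    return float(np.sqrt(var_plus / within))


def prob_direction(draws: np.ndarray, reference: str = "median") -> float:
    """Probability of direction: fraction of draws sharing the reference sign.

    ``reference`` is ``"median"`` (primary convention) or ``"mean"``.  Zeros
    are counted with the reference sign; an all-zero posterior returns 1.0
    with a warning.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("prob_direction requires >= 2 draws")
    if np.all(x == 0.0):
        warnings.warn("all draws are zero; pd set to 1.0", stacklevel=2)
        return 1.0
    if reference == "median":
        ref = np.median(x)
    elif reference == "mean":
        ref = x.mean()
    else:
        raise ValueError(f"unknown reference {reference!r}")
    sign = np.sign(ref)
    if sign == 0.0:  # reference exactly zero: fall back to the other moment
        sign = np.sign(x.mean() if reference == "median" else np.median(x))
    if sign == 0.0:
        return 0.5
    return float(np.mean((np.sign(x) == sign) | (x == 0.0)))


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from draw quantiles (linear rule)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    x = np.asarray(draws, dtype=float).ravel()
    lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2], method="linear")
    return float(lo), float(hi)


def evidence_category(ci: tuple[float, float], pd_value: float,
                      moderate_pd: float = 0.85) -> str:
    """Evidence label for a covariate effect.

    ``"strong"`` when the credible interval excludes zero, ``"moderate"``
    when it overlaps zero but pd exceeds ``moderate_pd``, else ``"weak"``.
    """
    lo, hi = ci
    if lo > 0.0 or hi < 0.0:
        return "strong"
    if pd_value > moderate_pd:
        return "moderate"
    return "weak"


def bayesian_pvalue(t_obs: np.ndarray, t_rep: np.ndarray) -> float:
    """Posterior-predictive p-value Pr[T(y_rep, θ) >= T(y, θ)].

    ``t_obs`` and ``t_rep`` are per-draw discrepancy statistics evaluated at
    the observed and replicated data respectively.  Values approaching 0 or 1
    indicate lack of fit.
    """
    t_obs = np.asarray(t_obs, dtype=float).ravel()
    t_rep = np.asarray(t_rep, dtype=float).ravel()
    if t_obs.shape != t_rep.shape:
        raise ValueError("t_obs and t_rep must be per-draw arrays of equal length")
    if t_obs.size < 100:
        warnings.warn(
            f"only {t_obs.size} draws: posterior-predictive p-value has large "
            "Monte-Carlo error", stacklevel=2,
        )
    return float(np.mean(t_rep >= t_obs))


def chi_square_discrepancy(y: np.ndarray, mu: np.ndarray, eps: float = 1e-9) -> float:
    """Chi-square discrepancy sum((y - mu)^2 / mu) for count data."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(np.sum((y - mu) ** 2 / np.maximum(mu, eps)))


def bernoulli_deviance(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    """Bernoulli deviance -2 sum(y log p + (1-y) log(1-p))."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return float(-2.0 * np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _summary_row(name: str, arr: np.ndarray, pd_reference: str) -> dict:
    flat = arr.ravel()
    q25, q50, q975 = np.quantile(flat, [0.025, 0.5, 0.975], method="linear")
    sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
    if sd == 0.0:
        rhat = float("nan")
        pd_val = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = gelman_rubin(arr) if arr.shape[0] >= 2 else float("nan")
            pd_val = prob_direction(flat, reference=pd_reference)
    return {
        "parameter": name,
        "mean": float(flat.mean()),
        "sd": sd,
        "q2.5": float(q25),
        "q50": float(q50),
        "q97.5": float(q975),
        "rhat": rhat,
        "pd": pd_val,
    }


def summarize_draws(draws: Mapping[str, np.ndarray],
                    pd_reference: str = "median") -> pd.DataFrame:
    """Posterior summary table from named per-chain draw arrays.

    Parameters
    ----------
    draws
        Mapping name -> array of shape ``(chains, n)`` for scalars or
        ``(chains, n, ...)`` for vector/matrix parameters; trailing axes are
        expanded into indexed rows (``beta[0]``, ``beta[1]``, ...).
    pd_reference
        Sign reference for pd ("median" primary; "mean" mirrors table-style
        reporting).

    Returns
    -------
    pandas.DataFrame
        One row per scalar parameter, columns :data:`SUMMARY_COLUMNS`.
    """
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim < 2:
            raise ValueError(f"{name}: draws must include a chain axis")
        if arr.ndim == 2:
            rows.append(_summary_row(name, arr, pd_reference))
        else:
            trailing = arr.shape[2:]
            for idx in np.ndindex(*trailing):
                label = f"{name}[{','.join(map(str, idx))}]"
                sub = arr[(slice(None), slice(None)) + idx]
                rows.append(_summary_row(label, sub, pd_reference))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def converged(summary: pd.DataFrame, threshold: float = RHAT_THRESHOLD) -> bool:
    """True when every finite R-hat in the summary is below ``threshold``."""
    rhats = summary["rhat"].to_numpy(dtype=float)
    finite = rhats[np.isfinite(rhats)]
    return bool(np.all(finite < threshold))
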