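"""Chained-equations multiple imputation with predictive mean matching.

This is the comparison arm: each item is imputed from all other items plus
the SNP and sex covariates, cycling through the item columns for a fixed
number of sweeps, repeated m times.  The imputation model is type-1
predictive mean matching — a Bayesian linear regression (normal-inverse-
gamma posterior draw for the coefficients and error variance) produces
predicted means; each missing cell borrows the observed value of one of
the k donors with the closest predicted mean, chosen uniformly.  Completed
datasets feed a mega-analysis sum-score regression pooled by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .assoc import AssocResult, ols_assoc, rubin_pool

__all__ = [
    "ImputationConfig",
    "pmm_impute_column",
    "chained_equations",
    "impute_mega_analysis",
]


@dataclass(frozen=True)
class ImputationConfig:
    """m imputed datasets, a fixed number of chained-equation sweeps each,
    and a k-donor pool for the matching step."""

    n_datasets: int = 50
    n_iterations: int = 5
    donor_pool: int = 5

    def __post_init__(self):
        if self.n_datasets < 2:
            raise ValueError("at least 2 imputed datasets are required")
        if self.donor_pool < 1:
            raise ValueError("donor pool must be at least 1")


def pmm_impute_column(
    target: np.ndarray,
    predictors: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill the missing entries of ``target`` by predictive mean matching.

    ``predictors`` must be complete (current working values for the other
    columns); an intercept is added internally.  Observed entries are
    returned untouched.
    """
    y = np.asarray(target, float)
    mis = np.isnan(y)
    if not mis.any():
        return y.copy()
    x = np.column_stack([np.ones(len(y)), np.asarray(predictors, float)])
    out = y.copy()
    out[mis] = _pmm_fill(y, x, mis, k, rng)
    return out


def _pmm_fill(y, x, mis, k, rng):
    """Imputed values for the rows flagged by ``mis``; ``x`` includes the
    intercept column."""
    obs = ~mis
    n_obs = int(obs.sum())
    if n_obs < k:
        raise ValueError(f"fewer than k={k} observed donors available")
    xo, yo = x[obs], y[obs]
    q = x.shape[1]
    xtx = xo.T @ xo + 1e-8 * np.eye(q)
    c = cho_factor(xtx)
    bhat = cho_solve(c, xo.T @ yo)
    resid = yo - xo @ bhat
    df = max(n_obs - q, 1)
    sigma2_hat = float(resid @ resid) / df
    # normal-inverse-gamma posterior draw
    sigma2_star = sigma2_hat * df / rng.chisquare(df)
    vmat = cho_solve(c, np.eye(q))
    bstar = bhat + np.linalg.cholesky(
        0.5 * (vmat + vmat.T) + 1e-12 * np.eye(q)
    ) @ rng.standard_normal(q) * np.sqrt(sigma2_star)
    yhat_obs = xo @ bhat  # type-1 matching: donors predicted with bhat
    yhat_mis = x[mis] @ bstar
    return _match_donors(yhat_obs, yo, yhat_mis, k, rng)


def _match_donors(yhat_obs, yo, yhat_mis, k, rng):
    """For each prediction, draw uniformly among the k observed values with
    the closest predicted means (exact k-nearest via a sorted window)."""
    n_obs = len(yhat_obs)
    n_mis = len(yhat_mis)
    order = np.argsort(yhat_obs)
    sorted_hat = yhat_obs[order]
    sorted_y = yo[order]
    if n_obs < 2 * k:
        d = np.abs(sorted_hat[None, :] - yhat_mis[:, None])
        part = np.argpartition(d, k - 1, axis=1)[:, :k]
        pick = part[np.arange(n_mis), rng.integers(0, k, n_mis)]
        return sorted_y[pick]
    pos = np.searchsorted(sorted_hat, yhat_mis)
    lo = np.clip(pos - k, 0, n_obs - 2 * k)
    cand = lo[:, None] + np.arange(2 * k)[None, :]
    d = np.abs(sorted_hat[cand] - yhat_mis[:, None])
    part = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = part[np.arange(n_mis), rng.integers(0, k, n_mis)]
    return sorted_y[cand[np.arange(n_mis), pick]]


def chained_equations(
    data: pd.DataFrame,
    item_columns: list[str],
    config: ImputationConfig,
    rng: np.random.Generator,
    covariate_columns: tuple[str, ...] = ("snp", "sex"),
) -> list[pd.DataFrame]:
    """Return m completed copies of ``data``.

    Missing cells are initialized by random draws from the observed values
    of their column, then each item is re-imputed from the other items plus
    the covariates for the configured number of sweeps.
    """
    items = data[item_columns].to_numpy(float)
    covs = data[list(covariate_columns)].to_numpy(float)
    n, n_items = items.shape
    masks = [np.isnan(items[:, j]) for j in range(n_items)]
    for j, col in enumerate(item_columns):
        if masks[j].all():
            raise ValueError(f"column {col!r} has no observed values")
    other = [np.delete(np.arange(n_items), j) for j in range(n_items)]
    xbuf = np.empty((n, 1 + (n_items - 1) + covs.shape[1]))
    xbuf[:, 0] = 1.0
    xbuf[:, n_items:] = covs
    completed: list[pd.DataFrame] = []
    for _ in range(config.n_datasets):
        work = items.copy()
        for j in range(n_items):
            m = masks[j]
            if m.any():
                obs_vals = items[~m, j]
                work[m, j] = rng.choice(obs_vals, size=int(m.sum()), replace=True)
        for _sweep in range(config.n_iterations):
            for j in range(n_items):
                m = masks[j]
                if not m.any():
                    continue
                xbuf[:, 1:n_items] = work[:, other[j]]
                work[m, j] = _pmm_fill(
                    items[:, j], xbuf, m, config.donor_pool, rng
                )
        out = data.copy()
        out[item_columns] = work
        completed.append(out)
    return completed


def impute_mega_analysis(
    data: pd.DataFrame,
    item_columns: list[str],
    config: ImputationConfig,
    rng: np.random.Generator,
) -> AssocResult:
    """Impute, sum the items, run one mega regression per completed dataset
    over all subjects, and Rubin-pool the SNP coefficients."""
    completed = chained_equations(data, item_columns, config, rng)
    estimates, variances = [], []
    n = len(data)
    for comp in completed:
        outcome = comp[item_columns].sum(axis=1)
        res = ols_assoc(outcome, comp["snp"], comp["sex"], outcome_kind="imputed_sum")
        estimates.append(res.beta)
        variances.append(res.se**2)
    beta, se, df, p = rubin_pool(
        np.array(estimates), np.array(variances), dfcom=n - 3
    )
    return AssocResult(beta, se, beta / se, p, n, outcome_kind="imputed_sum", study="mega")
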