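"""Per-study association tests and fixed-effects meta-analysis.

The manifest-phenotype arms regress a per-subject score (mean of available
items, or a regression factor score) on the SNP and sex within each study,
then pool the SNP coefficients by inverse-variance weighting.  Rubin's
rules for multiply imputed datasets live here too, since they are the
pooling step of the imputation arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocResult",
    "MetaResult",
    "sum_score",
    "ols_assoc",
    "fixed_effects_meta",
    "rubin_pool",
]


@dataclass(frozen=True)
class AssocResult:
    """A single SNP association estimate."""

    beta: float
    se: float
    stat: float
    p: float
    n: int
    outcome_kind: str = "sum_score"
    study: str = ""

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects inverse-variance pooled estimate."""

    beta: float
    se: float
    z: float
    p: float
    k_studies: int
    weights: np.ndarray = field(repr=False, default=None)


def sum_score(data: pd.DataFrame, item_columns) -> pd.Series:
    """Per-subject mean of the available items (NaN if none observed)."""
    return data[list(item_columns)].mean(axis=1, skipna=True)


def ols_assoc(
    outcome: np.ndarray | pd.Series,
    snp: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
    outcome_kind: str = "sum_score",
    study: str = "",
) -> AssocResult:
    """OLS of the outcome on intercept + SNP + sex; Wald t-test on the SNP
    coefficient with residual degrees of freedom.  Rows with a missing
    outcome are dropped."""
    y = np.asarray(outcome, float)
    keep = ~np.isnan(y)
    y = y[keep]
    x = np.column_stack([np.asarray(snp, float)[keep], np.asarray(sex, float)[keep]])
    if np.ptp(x[:, 0]) == 0:
        raise ValueError("snp column is constant; association is undefined")
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name a redundant column, preferring the covariates over the intercept
        for j, name in ((1, "snp"), (2, "sex"), (0, "const")):
            rest = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                raise ValueError(f"design matrix is rank deficient: column '{name}'")
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    tval = beta / se
    pval = 2.0 * stats.t.sf(abs(tval), fit.df_resid)
    return AssocResult(beta, se, tval, pval, int(len(y)), outcome_kind, study)


def fixed_effects_meta(results: list[AssocResult]) -> MetaResult:
    """Inverse-variance weighted fixed-effects pooling of k >= 2 studies."""
    if len(results) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    betas = np.array([r.beta for r in results])
    ses = np.array([r.se for r in results])
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(beta, se, z, p, len(results), w / w.sum())


def rubin_pool(
    estimates: np.ndarray, variances: np.ndarray, dfcom: float | None = None
):
    """Pool m >= 2 imputation estimates by Rubin's rules.

    Total variance T = W + (1 + 1/m) B; degrees of freedom by the
    Barnard-Rubin small-sample formula when the complete-data df ``dfcom``
    is given, else the classic large-sample form.  Returns
    ``(beta, se, df, p)`` with a t-based two-sided p-value.
    """
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    beta = float(est.mean())
    w = float(var.mean())
    b = float(est.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b == 0.0:
        df = np.inf if dfcom is None else float(dfcom)
    else:
        lam = (1.0 + 1.0 / m) * b / t
        df_old = (m - 1) / lam**2
        if dfcom is None:
            df = df_old
        else:
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = float(np.sqrt(t))
    tval = beta / se
    p = float(2.0 * stats.t.sf(abs(tval), df)) if np.isfinite(df) else float(
        2.0 * stats.norm.sf(abs(tval))
    )
    return beta, se, float(df), p
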