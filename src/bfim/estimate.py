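"""FIML estimation of the bi-factor integration model.

With continuous indicators and normal factors the observed-data likelihood
is available in closed form: rows are grouped by missingness pattern, and
each pattern contributes a multivariate-normal log-density on its observed
item subvector, with a per-subject mean when structural covariates are
present.  The per-pattern covariance is assembled once per evaluation, and
the analytic gradient (below) makes quasi-Newton maximization cheap enough
to run thousands of replicate fits.

The model surface follows the statsmodels convention:
``BiFactorModel(data, spec).fit()`` returns a :class:`BiFactorResults`
carrying estimates, observed-information standard errors, the
log-likelihood, convergence diagnostics, factor scores and fit measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .model import (
    BiFactorSpec,
    ParameterSet,
    derived_psi_zeta,
    pack_parameters,
    unpack_parameters,
    THETA_FLOOR,
)

__all__ = [
    "PatternPartition",
    "partition_patterns",
    "fiml_loglik",
    "BiFactorModel",
    "BiFactorResults",
    "fit_bfim",
    "saturated_fit",
    "baseline_fit",
    "fit_indices_from_chisq",
    "regression_factor_scores",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class _Pattern:
    observed: np.ndarray  # observed item indices, sorted
    rows: np.ndarray  # row indices into the retained data
    y: np.ndarray  # (n_p, k) observed item values
    x: np.ndarray | None  # (n_p, q) covariates, or None
    # sufficient statistics for the likelihood (set lazily; the Gaussian
    # FIML loglik and gradient depend on the data only through these, so
    # each evaluation costs O(k^3) regardless of n)
    s_y: np.ndarray | None = None  # sum of y rows, (k,)
    s_yy: np.ndarray | None = None  # y'y, (k, k)
    xt1: np.ndarray | None = None  # x'1, (q,)
    xtx: np.ndarray | None = None  # x'x, (q, q)
    xty: np.ndarray | None = None  # x'y, (q, k)

    def ensure_stats(self):
        if self.s_y is None:
            self.s_y = self.y.sum(axis=0)
            self.s_yy = self.y.T @ self.y
            if self.x is not None:
                self.xt1 = self.x.sum(axis=0)
                self.xtx = self.x.T @ self.x
                self.xty = self.x.T @ self.y


class PatternPartition:
    """Rows grouped by their observed-item pattern.

    Rows with no observed items are excluded (with a warning); the retained
    patterns are exhaustive and disjoint.
    """

    def __init__(self, y: np.ndarray, x: np.ndarray | None = None):
        y = np.asarray(y, float)
        n, p = y.shape
        observed_mask = ~np.isnan(y)
        keep = observed_mask.any(axis=1)
        self.n_dropped = int(n - keep.sum())
        if self.n_dropped:
            warnings.warn(
                f"excluded {self.n_dropped} row(s) with no observed items",
                stacklevel=2,
            )
        rows_all = np.flatnonzero(keep)
        codes = observed_mask[keep] @ (1 << np.arange(p, dtype=np.int64))
        self.patterns: list[_Pattern] = []
        for code in np.unique(codes):
            sel = rows_all[codes == code]
            obs = np.flatnonzero(observed_mask[sel[0]])
            self.patterns.append(
                _Pattern(
                    observed=obs,
                    rows=sel,
                    y=y[np.ix_(sel, obs)],
                    x=None if x is None else np.asarray(x, float)[sel],
                )
            )
        self.n_rows = int(keep.sum())
        self.n_items = p

    def __len__(self) -> int:
        return len(self.patterns)


def partition_patterns(
    data: pd.DataFrame, item_names, covariate_names=()
) -> PatternPartition:
    """Partition a wide table into missingness-pattern groups."""
    y = data[list(item_names)].to_numpy(float)
    x = data[list(covariate_names)].to_numpy(float) if covariate_names else None
    return PatternPartition(y, x)


# ----------------------------------------------------------------------
# likelihood and analytic gradient
# ----------------------------------------------------------------------

def _loglik_grad(
    vec: np.ndarray,
    spec: BiFactorSpec,
    partition: PatternPartition,
    s_x: np.ndarray | None,
    want_grad: bool = True,
):
    """Total observed-data log-likelihood and its gradient in packing order."""
    p, q = spec.n_items, spec.n_covariates
    sidx = np.asarray(spec.item_to_specific)
    nu, lam_g, lam_s, theta = (vec[i * p : (i + 1) * p] for i in range(4))
    theta = np.maximum(theta, THETA_FLOOR)
    gamma = vec[4 * p : 4 * p + q]
    offd = vec[4 * p + q :]
    psi = derived_psi_zeta(gamma, s_x)
    if q and psi <= 1e-6:
        # scale boundary: smooth barrier pushing gamma back inside
        val = -1e10 * (1.0 + (1e-6 - psi))
        if not want_grad:
            return val, None
        g = np.zeros_like(vec)
        g[4 * p : 4 * p + q] = -1e10 * 2.0 * (np.atleast_2d(s_x) @ gamma)
        return val, g

    d = np.ones(1 + spec.n_specific)
    if q:
        d[0] = psi

    ll = 0.0
    g_nu = np.zeros(p)
    g_lg = np.zeros(p)
    g_ls = np.zeros(p)
    g_th = np.zeros(p)
    g_gamma = np.zeros(q)
    g_offd = np.zeros(len(offd))
    g_psi = 0.0

    for pat in partition.patterns:
        pat.ensure_stats()
        o = pat.observed
        k = o.size
        n_p = pat.rows.size
        lam = np.zeros((k, 1 + spec.n_specific))
        lam[:, 0] = lam_g[o]
        lam[np.arange(k), 1 + sidx[o]] = lam_s[o]
        sigma = (lam * d) @ lam.T + np.diag(theta[o])
        in_pattern = []
        if len(offd):
            pos = {int(item): at for at, item in enumerate(o)}
            for r_idx, (pi, pj) in enumerate(spec.residual_cov_pairs):
                if pi in pos and pj in pos:
                    a, bpos = pos[pi], pos[pj]
                    sigma[a, bpos] += offd[r_idx]
                    sigma[bpos, a] += offd[r_idx]
                    in_pattern.append((r_idx, a, bpos))
        try:
            c = cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf, (np.zeros_like(vec) if want_grad else None)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))

        # scatter matrix of residuals r_j = y_j - nu - t_j lam_g with
        # t_j = gamma'x_j, expanded in the cached cross-moments
        nu_o, lg_o = nu[o], lam_g[o]
        if q:
            s_t = float(pat.xt1 @ gamma)
            s_t2 = float(gamma @ pat.xtx @ gamma)
            s_ty = gamma @ pat.xty  # (k,)
        else:
            s_t = s_t2 = 0.0
            s_ty = np.zeros(k)
        m = pat.s_y - n_p * nu_o - s_t * lg_o
        smat = (
            pat.s_yy
            - np.outer(pat.s_y, nu_o) - np.outer(nu_o, pat.s_y)
            + n_p * np.outer(nu_o, nu_o)
            - np.outer(s_ty, lg_o) - np.outer(lg_o, s_ty)
            + s_t * (np.outer(nu_o, lg_o) + np.outer(lg_o, nu_o))
            + s_t2 * np.outer(lg_o, lg_o)
        )
        sig_inv = cho_solve(c, np.eye(k))
        quad = float(np.sum(sig_inv * smat))
        ll += -0.5 * (n_p * (k * _LOG2PI + logdet) + quad)
        if not want_grad:
            continue

        gmat = 0.5 * (sig_inv @ smat @ sig_inv - n_p * sig_inv)  # d ll / d Sigma
        glam = 2.0 * (gmat @ lam) * d  # d ll / d Lambda entries
        g_lg[o] += glam[:, 0]
        g_ls[o] += glam[np.arange(k), 1 + sidx[o]]
        g_th[o] += np.diag(gmat)
        for r_idx, a, bpos in in_pattern:
            g_offd[r_idx] += 2.0 * gmat[a, bpos]
        # mean contributions
        sig_inv_lam = sig_inv @ lg_o
        g_nu[o] += sig_inv @ m
        if q:
            w = s_ty - s_t * nu_o - s_t2 * lg_o
            g_lg[o] += sig_inv @ w
            g_gamma += (
                pat.xty @ sig_inv_lam
                - pat.xt1 * float(nu_o @ sig_inv_lam)
                - (pat.xtx @ gamma) * float(lg_o @ sig_inv_lam)
            )
            g_psi += float(lg_o @ gmat @ lg_o)

    if not want_grad:
        return ll, None
    if q:
        g_gamma += g_psi * (-2.0 * (np.atleast_2d(s_x) @ gamma))
    grad = np.concatenate([g_nu, g_lg, g_ls, g_th, g_gamma, g_offd])
    return ll, grad


def fiml_loglik(
    params: ParameterSet, partition: PatternPartition, s_x: np.ndarray | None = None
) -> float:
    """Observed-data log-likelihood at a given parameter set.

    Without an explicit covariate covariance ``s_x``, the disturbance
    variance stored in ``params`` is honoured as-is.
    """
    if s_x is None and params.spec.n_covariates:
        g = params.gamma
        denom = float(g @ g)
        s_x = (
            ((1.0 - params.psi_zeta) / denom) * np.eye(len(g))
            if denom > 0
            else np.zeros((len(g), len(g)))
        )
    ll, _ = _loglik_grad(
        pack_parameters(params), params.spec, partition, s_x, want_grad=False
    )
    return ll


# ----------------------------------------------------------------------
# model / results objects
# ----------------------------------------------------------------------

class BiFactorModel:
    """Bi-factor integration model bound to a wide phenotype table.

    Parameters
    ----------
    data
        Wide table with one row per subject; item columns may contain NaN
        (missing by design), covariate columns must be complete.
    spec
        Model structure (items, specific-factor assignment, covariates).
    """

    def __init__(self, data: pd.DataFrame, spec: BiFactorSpec):
        self.spec = spec
        missing = [c for c in (*spec.item_names, *spec.covariate_names) if c not in data]
        if missing:
            raise KeyError(f"columns absent from data: {missing}")
        y = data[list(spec.item_names)].to_numpy(float)
        if spec.covariate_names:
            x = data[list(spec.covariate_names)].to_numpy(float)
            if np.isnan(x).any():
                raise ValueError("covariates must be complete")
            self.s_x = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
        else:
            x = None
            self.s_x = None
        self.partition = PatternPartition(y, x)
        self.nobs = self.partition.n_rows
        self._y = y

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        groups: dict[str, list[str]],
        covariates: list[str] | tuple[str, ...] = (),
        residual_cov_pairs: list[tuple[str, str]] | tuple = (),
    ) -> "BiFactorModel":
        """Construct from {questionnaire name: [item columns]} groups."""
        return cls(
            data,
            BiFactorSpec.from_groups(groups, tuple(covariates), residual_cov_pairs),
        )

    # -- likelihood interface -----------------------------------------
    def loglike(self, vec: np.ndarray) -> float:
        ll, _ = _loglik_grad(np.asarray(vec, float), self.spec, self.partition,
                             self.s_x, want_grad=False)
        return ll

    def score(self, vec: np.ndarray) -> np.ndarray:
        _, g = _loglik_grad(np.asarray(vec, float), self.spec, self.partition, self.s_x)
        return g

    def start_params(self) -> np.ndarray:
        """Feasible generic starts: item means/half-variances, loadings 0.5."""
        p = self.spec.n_items
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(self._y, axis=0)
            variances = np.nanvar(self._y, axis=0)
        means = np.where(np.isfinite(means), means, 0.0)
        variances = np.where(np.isfinite(variances) & (variances > 0), variances, 1.0)
        return np.concatenate(
            [
                means,
                np.full(p, 0.5),
                np.full(p, 0.5),
                np.maximum(0.5 * variances, 10 * THETA_FLOOR),
                np.zeros(self.spec.n_covariates),
                np.zeros(len(self.spec.residual_cov_pairs)),
            ]
        )

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 2000,
        gtol: float = 1e-5,
        compute_se: bool = True,
        n_retries: int = 1,
        retry_seed: int = 0,
    ) -> "BiFactorResults":
        """Maximize the FIML likelihood by L-BFGS-B with analytic gradient.

        Convergence requires optimizer success and a per-observation
        gradient inf-norm below ``gtol``; one jittered restart is attempted
        on failure.  Standard errors come from a central-difference Hessian
        of the analytic gradient (observed information).
        """
        x0 = self.start_params() if start_params is None else np.asarray(start_params, float)
        n = self.nobs
        p = self.spec.n_items
        bounds = (
            [(None, None)] * (3 * p)
            + [(THETA_FLOOR, None)] * p
            + [(None, None)]
            * (self.spec.n_covariates + len(self.spec.residual_cov_pairs))
        )

        def neg(vec):
            ll, g = _loglik_grad(vec, self.spec, self.partition, self.s_x)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(vec)
            return -ll / n, -g / n

        rng = np.random.default_rng(retry_seed)
        best = None
        n_iter_total = 0
        for attempt in range(1 + n_retries):
            res = optimize.minimize(
                neg,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-7,
                         "maxcor": 25},
            )
            n_iter_total += res.nit
            vec, gnorm, extra_it = self._newton_polish(res.x, gtol)
            n_iter_total += extra_it
            ok = bool(res.success or res.status == 0) and gnorm < gtol
            if best is None or -self.loglike(vec) / n < -self.loglike(best[0]) / n:
                best = (vec, gnorm, ok)
            if ok:
                break
            x0 = self.start_params() + rng.normal(0.0, 0.05, size=len(x0))
        vec, gnorm, converged = best

        vec = self._normalize_signs(vec)
        llf = self.loglike(vec)
        se = None
        if compute_se:
            # residual variances stuck at the Heywood floor are treated as
            # fixed; SEs come from the free-parameter block of the observed
            # information and are NaN for the bounded parameters
            free = ~self._active_bounds(vec, self.score(vec))
            hess = self._observed_information(vec)
            se_ok = False
            try:
                sub = hess[np.ix_(free, free)]
                cov = cho_solve(cho_factor(sub), np.eye(int(free.sum())))
                diag = np.diag(cov)
                if np.all(diag > 0):
                    se = np.full(len(vec), np.nan)
                    se[free] = np.sqrt(diag)
                    se_ok = True
            except np.linalg.LinAlgError:
                pass
            if not se_ok:
                converged = False
        params = unpack_parameters(vec, self.spec, self.s_x)
        return BiFactorResults(
            model=self,
            params=params,
            params_vector=vec,
            bse=se,
            llf=llf,
            converged=converged,
            n_iterations=n_iter_total,
            gradient_norm=gnorm,
        )

    def _active_bounds(self, vec: np.ndarray, g_ll: np.ndarray) -> np.ndarray:
        """Residual variances at the floor whose likelihood gradient points
        below the bound (KKT-satisfied active constraints)."""
        p = self.spec.n_items
        active = np.zeros(len(vec), bool)
        th = slice(3 * p, 4 * p)
        active[th] = (vec[th] <= THETA_FLOOR * (1.0 + 1e-9)) & (g_ll[th] <= 0)
        return active

    def _proj_gnorm(self, vec: np.ndarray, g_ll: np.ndarray) -> float:
        g = g_ll.copy()
        g[self._active_bounds(vec, g_ll)] = 0.0
        return float(np.max(np.abs(g)) / self.nobs)

    def _newton_polish(self, vec: np.ndarray, gtol: float, max_steps: int = 5):
        """Drive the scaled projected gradient below ``gtol`` with damped
        Newton steps on the free parameters (quasi-Newton stops are limited
        by surface conditioning; the exact observed information finishes the
        job).  The log-likelihood never decreases: steps are halved until it
        improves or the step is abandoned."""
        p = self.spec.n_items
        it = 0
        ll = self.loglike(vec)
        for _ in range(max_steps):
            g = self.score(vec)
            if self._proj_gnorm(vec, g) < gtol:
                break
            free = ~self._active_bounds(vec, g)
            hess = self._observed_information(vec)
            try:
                sub = cho_factor(hess[np.ix_(free, free)])
            except np.linalg.LinAlgError:
                break
            step = np.zeros_like(vec)
            step[free] = cho_solve(sub, g[free])
            scale = 1.0
            improved = False
            for _half in range(20):
                cand = vec + scale * step
                cand[3 * p : 4 * p] = np.maximum(cand[3 * p : 4 * p], THETA_FLOOR)
                ll_new = self.loglike(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * abs(ll):
                    vec, ll = cand, ll_new
                    improved = True
                    break
                scale *= 0.5
            it += 1
            if not improved:
                break
        return vec, self._proj_gnorm(vec, self.score(vec)), it

    def _normalize_signs(self, vec: np.ndarray) -> np.ndarray:
        """Fix the sign indeterminacy: each factor's loadings sum positive."""
        p = self.spec.n_items
        q = self.spec.n_covariates
        vec = vec.copy()
        lam_g = vec[p : 2 * p]
        if lam_g.sum() < 0:
            vec[p : 2 * p] = -lam_g
            # gamma flips with the general factor; residual covariances do not
            vec[4 * p : 4 * p + q] = -vec[4 * p : 4 * p + q]
        sidx = np.asarray(self.spec.item_to_specific)
        lam_s = vec[2 * p : 3 * p]
        for k in range(self.spec.n_specific):
            block = sidx == k
            if lam_s[block].sum() < 0:
                lam_s[block] = -lam_s[block]
        vec[2 * p : 3 * p] = lam_s
        return vec

    def _observed_information(self, vec: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Negative Hessian of the total loglik by central differences of
        the analytic gradient."""
        m = len(vec)
        hess = np.empty((m, m))
        for j in range(m):
            h = step * max(1.0, abs(vec[j]))
            up, dn = vec.copy(), vec.copy()
            up[j] += h
            dn[j] -= h
            _, gu = _loglik_grad(up, self.spec, self.partition, self.s_x)
            _, gd = _loglik_grad(dn, self.spec, self.partition, self.s_x)
            hess[:, j] = -(gu - gd) / (2.0 * h)
        return 0.5 * (hess + hess.T)


class BiFactorResults:
    """Fit results: estimates, SEs, log-likelihood, diagnostics, scoring."""

    def __init__(self, model, params, params_vector, bse, llf, converged,
                 n_iterations, gradient_norm):
        self.model = model
        self.params = params
        self.params_vector = params_vector
        self.bse = bse
        self.llf = llf
        self.converged = converged
        self.n_iterations = n_iterations
        self.gradient_norm = gradient_norm

    @property
    def spec(self) -> BiFactorSpec:
        return self.model.spec

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def se_for(self, block: str) -> np.ndarray | None:
        """Standard errors for one parameter block
        ('nu', 'lambda_g', 'lambda_s', 'theta', 'gamma')."""
        if self.bse is None:
            return None
        p = self.spec.n_items
        q = self.spec.n_covariates
        slices = {
            "nu": slice(0, p),
            "lambda_g": slice(p, 2 * p),
            "lambda_s": slice(2 * p, 3 * p),
            "theta": slice(3 * p, 4 * p),
            "gamma": slice(4 * p, 4 * p + q),
            "theta_offdiag": slice(4 * p + q, None),
        }
        return self.bse[slices[block]]

    def wald_gamma(self, name: str):
        """(estimate, se, z, two-sided p) for one structural coefficient."""
        i = self.spec.covariate_names.index(name)
        est = float(self.params.gamma[i])
        se_block = self.se_for("gamma")
        if se_block is None:
            return est, np.nan, np.nan, np.nan
        se = float(se_block[i])
        z = est / se
        pval = 2.0 * stats.norm.sf(abs(z))
        return est, se, z, pval

    def factor_scores(self, data: pd.DataFrame | None = None) -> pd.DataFrame:
        """Regression factor scores; see :func:`regression_factor_scores`."""
        if data is None:
            y = self.model._y
            ids = None
        else:
            y = data[list(self.spec.item_names)].to_numpy(float)
            ids = data["id"].to_numpy() if "id" in data else None
        return regression_factor_scores(self.params, y, ids=ids)

    def fit_measures(self) -> dict[str, float]:
        """Chi-square, df, RMSEA, CFI and TLI against the FIML saturated
        model, with the free-means/variances independence model as baseline.
        Only defined for measurement-only fits."""
        if self.spec.n_covariates:
            raise ValueError("fit measures are defined for measurement-only fits")
        part = self.model.partition
        _, _, ll_sat = saturated_fit(part)
        ll_base, df_base_free = baseline_fit(part)
        p = self.spec.n_items
        n_moments = p + p * (p + 1) // 2
        df_model = n_moments - self.spec.n_free
        df_base = n_moments - df_base_free
        chi2 = 2.0 * (ll_sat - self.llf)
        chi2_base = 2.0 * (ll_sat - ll_base)
        return fit_indices_from_chisq(chi2, df_model, self.nobs, chi2_base, df_base)

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Bi-Factor Integration Model (FIML)",
            "=" * 58,
            f"N subjects: {self.nobs}    patterns: {len(self.model.partition)}",
            f"log-likelihood: {self.llf:.3f}    converged: {self.converged}",
            f"iterations: {self.n_iterations}    |grad|_inf: {self.gradient_norm:.2e}",
            "-" * 58,
            f"{'item':<8}{'nu':>9}{'lambda_g':>10}{'lambda_s':>10}{'theta':>9}",
        ]
        for i, name in enumerate(spec.item_names):
            lines.append(
                f"{name:<8}{self.params.nu[i]:>9.4f}{self.params.lambda_g[i]:>10.4f}"
                f"{self.params.lambda_s[i]:>10.4f}{self.params.theta[i]:>9.4f}"
            )
        if spec.n_covariates:
            lines.append("-" * 58)
            lines.append(f"{'covariate':<12}{'gamma':>10}{'se':>10}{'z':>8}{'p':>10}")
            for name in spec.covariate_names:
                est, se, z, pval = self.wald_gamma(name)
                lines.append(f"{name:<12}{est:>10.4f}{se:>10.4f}{z:>8.2f}{pval:>10.2e}")
            lines.append(f"psi_zeta (derived): {self.params.psi_zeta:.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)


def fit_bfim(data: pd.DataFrame, spec: BiFactorSpec, **options) -> BiFactorResults:
    """Convenience wrapper: ``BiFactorModel(data, spec).fit(**options)``."""
    return BiFactorModel(data, spec).fit(**options)


# ----------------------------------------------------------------------
# saturated / baseline models and fit indices
# ----------------------------------------------------------------------

def _observed_ll(partition: PatternPartition, mu: np.ndarray, sigma: np.ndarray) -> float:
    ll = 0.0
    for pat in partition.patterns:
        o = pat.observed
        c = cho_factor(sigma[np.ix_(o, o)], lower=True)
        r = pat.y - mu[o]
        quad = float(np.sum(r.T * cho_solve(c, r.T)))
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        ll += -0.5 * (pat.rows.size * (o.size * _LOG2PI + logdet) + quad)
    return ll


def saturated_fit(
    partition: PatternPartition, max_iter: int = 1000, tol: float = 1e-8
):
    """EM for the unstructured multivariate-normal (mu, Sigma) under MAR.

    Returns ``(mu, Sigma, loglik)`` at convergence (absolute loglik change
    below ``tol``).  Raises on non-convergence so callers can mark fit
    indices as unavailable.
    """
    p = partition.n_items
    n = partition.n_rows
    # moment starts from available data
    counts = np.zeros(p)
    sums = np.zeros(p)
    for pat in partition.patterns:
        counts[pat.observed] += pat.rows.size
        sums[pat.observed] += pat.y.sum(axis=0)
    mu = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    sigma = np.eye(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        for pat in partition.patterns:
            o = pat.observed
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            n_p = pat.rows.size
            t1[o] += pat.y.sum(axis=0)
            t2[np.ix_(o, o)] += pat.y.T @ pat.y
            if m.size:
                c = cho_factor(sigma[np.ix_(o, o)], lower=True)
                beta = cho_solve(c, sigma[np.ix_(o, m)])  # (k, |m|)
                e_m = mu[m] + (pat.y - mu[o]) @ beta
                cond_cov = sigma[np.ix_(m, m)] - sigma[np.ix_(m, o)] @ beta
                t1[m] += e_m.sum(axis=0)
                t2[np.ix_(o, m)] += pat.y.T @ e_m
                t2[np.ix_(m, o)] += e_m.T @ pat.y
                t2[np.ix_(m, m)] += e_m.T @ e_m + n_p * cond_cov
        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = _observed_ll(partition, mu, sigma)
        if abs(ll - ll_old) < tol:
            return mu, sigma, ll
        ll_old = ll
    raise RuntimeError("saturated-model EM did not converge")


def baseline_fit(partition: PatternPartition):
    """Independence model (free means and variances, zero covariances).

    With a diagonal covariance the observed-data likelihood factors by
    item, so the FIML solution is the per-item ML mean and variance over
    that item's observed rows.  Returns ``(loglik, n_free)``.
    """
    p = partition.n_items
    sums = np.zeros(p)
    sq = np.zeros(p)
    counts = np.zeros(p)
    for pat in partition.patterns:
        o = pat.observed
        counts[o] += pat.rows.size
        sums[o] += pat.y.sum(axis=0)
        sq[o] += (pat.y**2).sum(axis=0)
    mu = sums / counts
    var = sq / counts - mu**2
    ll = float(np.sum(-0.5 * counts * (_LOG2PI + np.log(var) + 1.0)))
    return ll, 2 * p


def fit_indices_from_chisq(
    chi2: float, df: int, n: int, chi2_base: float, df_base: int
) -> dict[str, float]:
    """RMSEA, CFI and TLI from model and baseline chi-square statistics."""
    if df <= 0 or df_base <= 0:
        raise ValueError("degrees of freedom must be positive")
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    tli_den = chi2_base / df_base - 1.0
    tli = ((chi2_base / df_base) - (chi2 / df)) / tli_den if tli_den != 0 else 1.0
    return {
        "chi2": float(chi2),
        "df": int(df),
        "rmsea": rmsea,
        "cfi": float(cfi),
        "tli": float(tli),
    }


# ----------------------------------------------------------------------
# factor scores
# ----------------------------------------------------------------------

def regression_factor_scores(
    params: ParameterSet, y: np.ndarray, ids=None
) -> pd.DataFrame:
    """Regression (conditional-mean) factor scores per subject.

    For observed items o: score = Psi Lambda_o' Sigma_o^{-1} (y_o - nu_o)
    with Psi = I under the standardized-factor identification.  Subjects
    with no observed items get the prior mean 0 and are flagged by
    ``n_observed_items`` = 0.
    """
    y = np.asarray(y, float)
    n = y.shape[0]
    ks = params.spec.n_specific
    scores = np.zeros((n, 1 + ks))
    n_obs = (~np.isnan(y)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        part = PatternPartition(y)
    from .model import implied_covariance

    for pat in part.patterns:
        o = pat.observed
        lam = params.loading_matrix(o)
        sigma = implied_covariance(params, o)  # marginal, incl. freed pairs
        c = cho_factor(sigma, lower=True)
        r = pat.y - params.nu[o]
        scores[pat.rows] = r @ cho_solve(c, lam)
    cols = ["T"] + [f"eta{k + 1}" for k in range(ks)]
    out = pd.DataFrame(scores, columns=cols)
    out["n_observed_items"] = n_obs
    if ids is not None:
        out.insert(0, "id", np.asarray(ids))
    return out
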