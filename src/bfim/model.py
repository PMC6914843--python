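"""Bi-factor integration model: specification, parameters, implied moments.

Every item loads on one general factor (the harmonized target trait) and on
exactly one questionnaire-specific factor; all factors are mutually
orthogonal and standard normal a priori.  When structural covariates are
present the trait is regressed on them, T = gamma'x + zeta, and the model is
standardized so the marginal trait variance stays 1: the disturbance
variance is derived, psi_zeta = 1 - gamma' S_x gamma, with S_x the sample
covariance of the covariates.  Estimated gamma is therefore on the same
scale as the generating coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BiFactorSpec",
    "ParameterSet",
    "InfeasibleScaleError",
    "implied_covariance",
    "implied_mean",
    "pack_parameters",
    "unpack_parameters",
]

#: lower bound for residual variances (Heywood guard)
THETA_FLOOR = 1e-4


class InfeasibleScaleError(ValueError):
    """gamma' S_x gamma >= 1: no admissible disturbance variance exists."""


@dataclass(frozen=True)
class BiFactorSpec:
    """Structure of a bi-factor integration model.

    Parameters
    ----------
    item_names
        Ordered item (column) names.
    item_to_specific
        For each item, the index of the single specific factor it loads on.
    covariate_names
        Structural covariates of the general factor (empty for
        measurement-only models).
    """

    item_names: tuple[str, ...]
    item_to_specific: tuple[int, ...]
    covariate_names: tuple[str, ...] = ()
    #: item-index pairs whose residual covariance is freed (e.g. a known
    #: similarly-worded "bridge" pair across questionnaires)
    residual_cov_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if len(self.item_names) != len(self.item_to_specific):
            raise ValueError("one specific-factor index required per item")
        counts = np.bincount(np.asarray(self.item_to_specific))
        if len(counts) < 1 or np.any(counts < 2):
            raise ValueError("each specific factor needs at least 2 items")
        for i, j in self.residual_cov_pairs:
            if i == j or not (0 <= i < len(self.item_names)) or not (
                0 <= j < len(self.item_names)
            ):
                raise ValueError(f"invalid residual covariance pair ({i}, {j})")

    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def n_specific(self) -> int:
        return int(max(self.item_to_specific)) + 1

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def n_free(self) -> int:
        return 4 * self.n_items + self.n_covariates + len(self.residual_cov_pairs)

    @classmethod
    def from_groups(
        cls,
        groups: dict[str, list[str]],
        covariates: tuple[str, ...] | list[str] = (),
        residual_cov_pairs: list[tuple[str, str]] | tuple = (),
    ) -> "BiFactorSpec":
        """Build a spec from {specific-factor name: [item names]} groups;
        ``residual_cov_pairs`` names item pairs whose residual covariance
        is freely estimated."""
        items: list[str] = []
        assign: list[int] = []
        for k, (name, cols) in enumerate(groups.items()):
            items.extend(cols)
            assign.extend([k] * len(cols))
        pairs = tuple(
            (items.index(a), items.index(b)) for a, b in residual_cov_pairs
        )
        return cls(tuple(items), tuple(assign), tuple(covariates), pairs)


@dataclass(frozen=True)
class ParameterSet:
    """Free parameters of a BFIM plus the derived disturbance variance."""

    nu: np.ndarray
    lambda_g: np.ndarray
    lambda_s: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray
    psi_zeta: float
    spec: BiFactorSpec
    theta_offdiag: np.ndarray | None = None

    def __post_init__(self):
        p = self.spec.n_items
        for name in ("nu", "lambda_g", "lambda_s", "theta"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} must have length {p}")
        if self.theta_offdiag is None:
            object.__setattr__(
                self, "theta_offdiag", np.zeros(len(self.spec.residual_cov_pairs))
            )
        if len(self.theta_offdiag) != len(self.spec.residual_cov_pairs):
            raise ValueError("one residual covariance per declared pair")
        if len(self.gamma) != self.spec.n_covariates:
            raise ValueError("gamma length must match the covariate list")
        if np.any(self.theta < THETA_FLOOR - 1e-12):
            raise ValueError("residual variances below the admissible floor")
        if self.psi_zeta <= 0:
            raise InfeasibleScaleError("derived disturbance variance <= 0")

    def loading_matrix(self, observed: np.ndarray | None = None) -> np.ndarray:
        """Items x (1 + K) loading matrix [lambda_g | specific columns]."""
        p, ks = self.spec.n_items, self.spec.n_specific
        lam = np.zeros((p, 1 + ks))
        lam[:, 0] = self.lambda_g
        lam[np.arange(p), 1 + np.asarray(self.spec.item_to_specific)] = self.lambda_s
        return lam if observed is None else lam[observed]


def _factor_cov(params: ParameterSet, conditional: bool) -> np.ndarray:
    d = np.ones(1 + params.spec.n_specific)
    if conditional and params.spec.n_covariates:
        d[0] = params.psi_zeta
    return d


def implied_covariance(
    params: ParameterSet,
    observed_items: np.ndarray | list[int] | None = None,
    conditional: bool = False,
) -> np.ndarray:
    """Model-implied covariance of the observed item subvector.

    By default the marginal covariance Lambda Psi Lambda' + Theta with
    Psi = I (unit-variance orthogonal factors).  With ``conditional`` the
    general factor contributes its disturbance variance psi_zeta instead,
    i.e. the covariance of y given the structural covariates — the form the
    observed-data likelihood uses.
    """
    obs = (
        np.arange(params.spec.n_items)
        if observed_items is None
        else np.asarray(observed_items)
    )
    if obs.size == 0:
        raise ValueError("observed item set must be non-empty")
    lam = params.loading_matrix(obs)
    d = _factor_cov(params, conditional)
    sigma = (lam * d) @ lam.T + np.diag(params.theta[obs])
    pos = {int(item): at for at, item in enumerate(obs)}
    for (i, j), cov in zip(params.spec.residual_cov_pairs, params.theta_offdiag):
        if i in pos and j in pos:
            sigma[pos[i], pos[j]] += cov
            sigma[pos[j], pos[i]] += cov
    return sigma


def implied_mean(
    params: ParameterSet,
    x: np.ndarray | None = None,
    observed_items: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """E[y | x] = nu + lambda_g (gamma'x), restricted to the observed items."""
    obs = (
        np.arange(params.spec.n_items)
        if observed_items is None
        else np.asarray(observed_items)
    )
    mu = params.nu[obs].astype(float).copy()
    if params.spec.n_covariates:
        x = np.zeros(params.spec.n_covariates) if x is None else np.asarray(x, float)
        if x.shape[-1] != params.spec.n_covariates:
            raise ValueError("covariate vector length does not match gamma")
        mu = mu + params.lambda_g[obs] * float(params.gamma @ x)
    return mu


def pack_parameters(params: ParameterSet) -> np.ndarray:
    """Flatten to the free-parameter vector [nu, lambda_g, lambda_s, theta, gamma]."""
    return np.concatenate(
        [params.nu, params.lambda_g, params.lambda_s, params.theta, params.gamma,
         params.theta_offdiag]
    )


def derived_psi_zeta(gamma: np.ndarray, s_x: np.ndarray | None) -> float:
    if gamma.size == 0:
        return 1.0
    val = 1.0 - float(gamma @ np.atleast_2d(s_x) @ gamma)
    return val


def unpack_parameters(
    vector: np.ndarray, spec: BiFactorSpec, s_x: np.ndarray | None = None
) -> ParameterSet:
    """Inverse of :func:`pack_parameters`.

    Enforces the residual-variance floor and recomputes the derived
    disturbance variance psi_zeta = 1 - gamma' S_x gamma; raises
    :class:`InfeasibleScaleError` at or beyond the scale boundary.
    """
    p, q = spec.n_items, spec.n_covariates
    vector = np.asarray(vector, float)
    if vector.size != spec.n_free:
        raise ValueError(f"expected {spec.n_free} free parameters")
    nu, lam_g, lam_s, theta = (vector[i * p : (i + 1) * p] for i in range(4))
    gamma = vector[4 * p : 4 * p + q]
    offd = vector[4 * p + q :]
    theta = np.maximum(theta, THETA_FLOOR)
    psi = derived_psi_zeta(gamma, s_x)
    if q and psi <= 0:
        raise InfeasibleScaleError(
            "gamma' S_x gamma >= 1 leaves no disturbance variance"
        )
    return ParameterSet(nu, lam_g, lam_s, theta, gamma, psi, spec, offd)
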