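"""Synthetic multi-cohort phenotype data under the four generating models.

The simulated scenario: two cohorts measure the same latent trait with two
disjoint 4-item questionnaires, plus a small phenotypic reference panel with
complete data on all 8 items.  A single SNP (additive 0/1/2 coding, Hardy-
Weinberg equilibrium) explains 0.1% of the latent trait variance and a binary
sex covariate explains 20%; the remaining disturbance keeps the marginal trait
variance at exactly 1.  One item of each questionnaire forms a "bridge" pair
with an extra residual correlation of 0.6, mimicking two similarly worded
items across instruments.

Generating models
-----------------
1. identical measurement: every item has general-factor share 25.5%,
   specific-factor share 34.5%, residual 40%.
2. reliability differences: questionnaire 2's communality drops to 45%,
   split between general and specific factors in the 25.5:34.5 ratio.
3. model 2 plus a shifted questionnaire-2 specific factor (mean 1, variance 3).
4. a higher-order factor model (trait -> two questionnaire factors -> items,
   with direct trait effects on a subset of items), under which the fitted
   bi-factor model is mildly misspecified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneratingModelSpec",
    "HigherOrderBlock",
    "SampleSizeCondition",
    "SAMPLE_SIZE_CONDITIONS",
    "ITEM_COLUMNS",
    "BRIDGE_COLUMN",
    "build_generating_model",
    "generate_genotypes",
    "simulate_complete",
    "apply_missing_by_design",
    "generate_dataset",
    "make_no_panel_dataset",
]

ITEM_COLUMNS = [f"y{i}" for i in range(1, 9)]
#: name of the merged shared item in no-reference-panel designs
BRIDGE_COLUMN = "yb"

# structural regression of the trait on (SNP, sex): 0.0447^2 * 2*0.5*0.5 = 0.1%
# and 0.8944^2 * 0.25 = 20.0% of the unit trait variance
GAMMA_SNP = 0.0447
GAMMA_SEX = 0.8944
DEFAULT_MAF = 0.5
BRIDGE_RHO = 0.6

# model-1 item variance shares (general / specific / residual)
_SHARE_G = 0.255
_SHARE_S = 0.345
_WEAK_COMMUNALITY = 0.45


@dataclass(frozen=True)
class HigherOrderBlock:
    """Parameters of the higher-order generating model (model 4).

    The trait T feeds two first-order questionnaire factors F1, F2 through
    second-order loadings b_k, with disturbance variances chosen so each F_k
    has unit marginal variance.  Items load on their questionnaire factor
    with a common loading, and a subset of items receives an additional
    direct effect of T.

    Defaults are calibrated so the trait carries the same average share of
    item variance as under model 1 (mean effective trait loading squared
    = 25.5%): lam_F * b = 0.395, so items with the 0.2 direct effect have
    effective trait covariance 0.595 and the others 0.395, averaging to
    0.255 in squared terms.  This keeps the complete-data association power
    comparable across generating models, with the direct-effect subset
    breaking the higher-order proportionality constraints.
    """

    second_order_loadings: tuple[float, float] = (0.51, 0.51)
    disturbance_vars: tuple[float, float] = (1.0 - 0.51**2, 1.0 - 0.51**2)
    item_loading: float = float(np.sqrt(0.60))
    direct_effect_items: tuple[int, ...] = (0, 1, 4, 5)
    direct_effect: float = 0.2


@dataclass(frozen=True)
class GeneratingModelSpec:
    """Full numeric parameterization of one data-generating model."""

    model_id: int
    item_intercepts: np.ndarray
    loadings_general: np.ndarray
    loadings_specific: np.ndarray
    item_to_specific: np.ndarray  # 0 for questionnaire 1, 1 for questionnaire 2
    specific_means: np.ndarray
    specific_vars: np.ndarray
    residual_vars: np.ndarray
    bridge_pair: tuple[int, int] = (3, 4)
    bridge_rho: float = BRIDGE_RHO
    gamma_snp: float = GAMMA_SNP
    gamma_sex: float = GAMMA_SEX
    zeta_var: float = 0.799
    maf: float = DEFAULT_MAF
    higher_order: HigherOrderBlock | None = None

    def __post_init__(self):
        if self.model_id not in (1, 2, 3, 4):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not (0.0 <= self.bridge_rho < 1.0):
            raise ValueError("bridge residual correlation must lie in [0, 1)")
        i, j = self.bridge_pair
        if self.item_to_specific[i] == self.item_to_specific[j]:
            raise ValueError("bridge pair must span the two questionnaires")
        var_snp = 2.0 * self.maf * (1.0 - self.maf)
        total = (
            self.gamma_snp**2 * var_snp
            + self.gamma_sex**2 * 0.25
            + self.zeta_var
        )
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"trait variance decomposition sums to {total:.6f}, not 1"
            )
        if self.model_id in (1, 2, 3):
            psi = self.specific_vars[self.item_to_specific]
            implied = (
                self.loadings_general**2
                + self.loadings_specific**2 * psi
                + self.residual_vars
            )
            if self.model_id in (1, 2) and np.max(np.abs(implied - 1.0)) > 1e-10:
                raise ValueError("items must have unit marginal variance")
        elif self.higher_order is None:
            raise ValueError("model 4 requires a higher_order block")

    # ------------------------------------------------------------------
    # model-implied moments (closed form, used as the simulation oracle)
    # ------------------------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.item_intercepts)

    def trait_mean(self) -> float:
        return self.gamma_snp * 2.0 * self.maf + self.gamma_sex * 0.5

    def residual_cov(self) -> np.ndarray:
        sd = np.sqrt(self.residual_vars)
        cov = np.diag(self.residual_vars)
        i, j = self.bridge_pair
        cov[i, j] = cov[j, i] = self.bridge_rho * sd[i] * sd[j]
        return cov

    def implied_item_mean(self) -> np.ndarray:
        t = self.trait_mean()
        if self.model_id == 4:
            ho = self.higher_order
            b = np.asarray(ho.second_order_loadings)
            lam_f = ho.item_loading
            d = np.zeros(self.n_items)
            d[list(ho.direct_effect_items)] = ho.direct_effect
            return lam_f * b[self.item_to_specific] * t + d * t
        return (
            self.item_intercepts
            + self.loadings_general * t
            + self.loadings_specific * self.specific_means[self.item_to_specific]
        )

    def effective_general_loadings(self) -> np.ndarray:
        """Per-item covariance with the trait: Cov(y_i, T).  Equals the
        general loadings for the bi-factor generating models; for the
        higher-order model it is lam_F * b_k + d_i."""
        if self.model_id == 4:
            ho = self.higher_order
            b = np.asarray(ho.second_order_loadings)
            d = np.zeros(self.n_items)
            d[list(ho.direct_effect_items)] = ho.direct_effect
            return ho.item_loading * b[self.item_to_specific] + d
        return np.asarray(self.loadings_general, float)

    def implied_item_cov(self) -> np.ndarray:
        """Marginal covariance of the 8 items (over SNP, sex and all factors)."""
        if self.model_id == 4:
            ho = self.higher_order
            b = np.asarray(ho.second_order_loadings)
            d = np.zeros(self.n_items)
            d[list(ho.direct_effect_items)] = ho.direct_effect
            k = self.item_to_specific
            # y_i = lam_f * F_{k(i)} + d_i * T + eps_i, Var(T)=Var(F_k)=1,
            # Cov(F_k, T) = b_k, Cov(F_1, F_2) = b_1 b_2
            cov_f = np.where(
                k[:, None] == k[None, :], 1.0, b[k][:, None] * b[k][None, :]
            )
            lam_f = ho.item_loading
            common = (
                lam_f**2 * cov_f
                + lam_f * np.outer(b[k], d)
                + lam_f * np.outer(d, b[k])
                + np.outer(d, d)
            )
            return common + self.residual_cov()
        lam_g = self.loadings_general
        lam_s = self.loadings_specific
        psi = self.specific_vars
        same = self.item_to_specific[:, None] == self.item_to_specific[None, :]
        specific = np.where(
            same,
            np.outer(lam_s, lam_s) * psi[self.item_to_specific][:, None],
            0.0,
        )
        return np.outer(lam_g, lam_g) + specific + self.residual_cov()


@dataclass(frozen=True)
class SampleSizeCondition:
    condition_id: str
    n_cohort1: int
    n_cohort2: int
    n_ref: int

    @property
    def n_total(self) -> int:
        return self.n_cohort1 + self.n_cohort2 + self.n_ref


SAMPLE_SIZE_CONDITIONS: dict[str, SampleSizeCondition] = {
    "N1": SampleSizeCondition("N1", 5000, 5000, 400),
    "N2": SampleSizeCondition("N2", 2500, 2500, 400),
    "N3": SampleSizeCondition("N3", 7500, 7500, 400),
    "N4": SampleSizeCondition("N4", 2500, 7500, 400),
    "N5": SampleSizeCondition("N5", 4500, 4500, 1000),
}


def _zeta_var(gamma_snp: float, gamma_sex: float, maf: float) -> float:
    var_snp = 2.0 * maf * (1.0 - maf)
    return 1.0 - gamma_snp**2 * var_snp - gamma_sex**2 * 0.25


def build_generating_model(model_id: int, null_snp: bool = False) -> GeneratingModelSpec:
    """Return the fully numeric spec of one of the four generating models.

    With ``null_snp`` the SNP coefficient is set to zero and the disturbance
    variance raised so the trait keeps unit marginal variance (used for the
    type-I-error runs).
    """
    if model_id not in (1, 2, 3, 4):
        raise ValueError(f"unknown model_id {model_id!r}")
    g_snp = 0.0 if null_snp else GAMMA_SNP
    zeta = _zeta_var(g_snp, GAMMA_SEX, DEFAULT_MAF)
    item_to_specific = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    nu = np.zeros(8)

    lam_g_strong = np.sqrt(_SHARE_G)
    lam_s_strong = np.sqrt(_SHARE_S)
    if model_id == 1:
        lam_g = np.full(8, lam_g_strong)
        lam_s = np.full(8, lam_s_strong)
        resid = np.full(8, 1.0 - _SHARE_G - _SHARE_S)
        means, variances = np.zeros(2), np.ones(2)
        ho = None
    elif model_id in (2, 3):
        frac_g = _SHARE_G / (_SHARE_G + _SHARE_S)
        lam_g = np.concatenate(
            [np.full(4, lam_g_strong), np.full(4, np.sqrt(_WEAK_COMMUNALITY * frac_g))]
        )
        lam_s = np.concatenate(
            [
                np.full(4, lam_s_strong),
                np.full(4, np.sqrt(_WEAK_COMMUNALITY * (1.0 - frac_g))),
            ]
        )
        resid = np.concatenate([np.full(4, 0.40), np.full(4, 1.0 - _WEAK_COMMUNALITY)])
        if model_id == 3:
            means, variances = np.array([0.0, 1.0]), np.array([1.0, 3.0])
        else:
            means, variances = np.zeros(2), np.ones(2)
        ho = None
    else:  # model 4: higher-order generating model
        ho = HigherOrderBlock()
        b = np.asarray(ho.second_order_loadings)
        d = np.zeros(8)
        d[list(ho.direct_effect_items)] = ho.direct_effect
        lam_f = ho.item_loading
        bk = b[item_to_specific]
        # residual variance solved so each item has unit marginal variance
        common_var = lam_f**2 + d**2 + 2.0 * lam_f * d * bk
        resid = 1.0 - common_var
        lam_g = d  # direct effects of the trait
        lam_s = np.full(8, lam_f)  # loadings on the questionnaire factors
        means, variances = np.zeros(2), np.ones(2)

    return GeneratingModelSpec(
        model_id=model_id,
        item_intercepts=nu,
        loadings_general=lam_g,
        loadings_specific=lam_s,
        item_to_specific=item_to_specific,
        specific_means=means,
        specific_vars=variances,
        residual_vars=resid,
        gamma_snp=g_snp,
        zeta_var=zeta,
        higher_order=ho,
    )


def generate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Additively coded genotypes, Binomial(2, maf) under Hardy-Weinberg."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 < maf < 1.0):
        raise ValueError("maf must lie strictly between 0 and 1")
    return rng.binomial(2, maf, size=n)


def _cohort_labels(sizes: SampleSizeCondition) -> pd.Categorical:
    labels = (
        ["cohort1"] * sizes.n_cohort1
        + ["cohort2"] * sizes.n_cohort2
        + ["ref"] * sizes.n_ref
    )
    return pd.Categorical(labels, categories=["cohort1", "cohort2", "ref"])


def simulate_complete(
    spec: GeneratingModelSpec,
    sizes: SampleSizeCondition,
    rng: np.random.Generator,
    keep_latent: bool = False,
) -> pd.DataFrame:
    """Draw a complete (no missingness) dataset with cohort labels attached."""
    n = sizes.n_total
    sex = rng.integers(0, 2, size=n)
    snp = generate_genotypes(n, spec.maf, rng)
    zeta = rng.normal(0.0, np.sqrt(spec.zeta_var), size=n)
    trait = spec.gamma_snp * snp + spec.gamma_sex * sex + zeta

    resid_cov = spec.residual_cov()
    try:
        chol = np.linalg.cholesky(resid_cov)
    except np.linalg.LinAlgError as exc:  # cannot occur for rho < 1, guard anyway
        raise ValueError("residual covariance is not positive definite") from exc
    eps = rng.standard_normal((n, spec.n_items)) @ chol.T

    k = spec.item_to_specific
    if spec.model_id == 4:
        ho = spec.higher_order
        b = np.asarray(ho.second_order_loadings)
        u = rng.normal(0.0, np.sqrt(ho.disturbance_vars), size=(n, 2))
        factors = trait[:, None] * b[None, :] + u
        d = np.zeros(spec.n_items)
        d[list(ho.direct_effect_items)] = ho.direct_effect
        items = ho.item_loading * factors[:, k] + np.outer(trait, d) + eps
        eta = factors
    else:
        eta = rng.normal(
            spec.specific_means, np.sqrt(spec.specific_vars), size=(n, 2)
        )
        items = (
            spec.item_intercepts
            + np.outer(trait, spec.loadings_general)
            + eta[:, k] * spec.loadings_specific
            + eps
        )

    df = pd.DataFrame(items, columns=ITEM_COLUMNS)
    df.insert(0, "sex", sex)
    df.insert(0, "snp", snp)
    df.insert(0, "cohort", _cohort_labels(sizes))
    df.insert(0, "id", np.arange(1, n + 1))
    if keep_latent:
        df["T"] = trait
        df["eta1"] = eta[:, 0]
        df["eta2"] = eta[:, 1]
    return df


def apply_missing_by_design(df: pd.DataFrame) -> pd.DataFrame:
    """Mask the unobserved questionnaire per cohort (MAR given cohort)."""
    out = df.copy()
    c1 = out["cohort"] == "cohort1"
    c2 = out["cohort"] == "cohort2"
    out.loc[c1, ITEM_COLUMNS[4:]] = np.nan
    out.loc[c2, ITEM_COLUMNS[:4]] = np.nan
    return out


def generate_dataset(
    spec: GeneratingModelSpec,
    sizes: SampleSizeCondition,
    rng: np.random.Generator,
    keep_latent: bool = False,
) -> pd.DataFrame:
    """One wide missing-by-design dataset: cohort 1 observes items 1-4,
    cohort 2 items 5-8, the reference panel all 8."""
    return apply_missing_by_design(simulate_complete(spec, sizes, rng, keep_latent))


def _reallocate_no_panel(sizes: SampleSizeCondition) -> SampleSizeCondition:
    if sizes.n_cohort1 == sizes.n_cohort2:
        half = sizes.n_ref // 2
        return SampleSizeCondition(
            sizes.condition_id,
            sizes.n_cohort1 + half,
            sizes.n_cohort2 + (sizes.n_ref - half),
            0,
        )
    # unbalanced condition: all extra subjects join the smaller cohort
    if sizes.n_cohort1 < sizes.n_cohort2:
        return SampleSizeCondition(
            sizes.condition_id, sizes.n_cohort1 + sizes.n_ref, sizes.n_cohort2, 0
        )
    return SampleSizeCondition(
        sizes.condition_id, sizes.n_cohort1, sizes.n_cohort2 + sizes.n_ref, 0
    )


def make_no_panel_dataset(
    spec: GeneratingModelSpec,
    sizes: SampleSizeCondition,
    rng: np.random.Generator,
    keep_latent: bool = False,
) -> pd.DataFrame:
    """No-reference-panel variant: panel subjects are reallocated to the
    cohorts and the bridge pair is merged into one shared item column
    (``yb``), yielding 7 item columns observed in both cohorts."""
    new_sizes = _reallocate_no_panel(sizes)
    df = apply_missing_by_design(
        simulate_complete(spec, new_sizes, rng, keep_latent)
    )
    i, j = spec.bridge_pair
    col_i, col_j = ITEM_COLUMNS[i], ITEM_COLUMNS[j]
    merged = df[col_i].where(df["cohort"] == "cohort1", df[col_j])
    df = df.drop(columns=[col_i, col_j])
    insert_at = df.columns.get_loc(ITEM_COLUMNS[i - 1]) + 1 if i > 0 else 4
    df.insert(insert_at, BRIDGE_COLUMN, merged)
    return df


def no_panel_item_columns(spec: GeneratingModelSpec) -> list[str]:
    """Item columns of a merged-bridge dataset, in order."""
    i, j = spec.bridge_pair
    cols = [c for k, c in enumerate(ITEM_COLUMNS) if k not in (i, j)]
    cols.insert(i, BRIDGE_COLUMN)
    return cols
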