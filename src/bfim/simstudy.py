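"""Monte-Carlo study: the 4 models x 5 sample-size grid across analysis arms.

Each replication generates one dataset per condition (plus an independent
null-SNP dataset for the type-I-error runs) and pushes it through the
requested arms:

- ``complete_sem``  bi-factor SEM on complete data (maximum-power benchmark)
- ``mega_sem``      BFIM mega-analysis on missing-by-design data + panel
- ``fs_meta``       measurement-only BFIM, regression factor scores,
                    per-study OLS, fixed-effects meta-analysis
- ``ss_meta``       mean of available items, per-study OLS, meta-analysis
- ``impute``        chained-equations PMM imputation, imputed-sum-score
                    mega regression, Rubin pooling
- ``mega_no_panel`` / ``fs_no_panel``  the no-reference-panel variants with
                    the bridge pair merged into one shared item

Per-replication seeds are derived from (base seed, model, condition,
replication, null flag) so arms and replications are independent,
reproducible work units regardless of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datagen
from .assoc import fixed_effects_meta, ols_assoc, sum_score
from .estimate import BiFactorModel
from .impute import ImputationConfig, impute_mega_analysis
from .model import BiFactorSpec

__all__ = [
    "METHODS",
    "ConditionResult",
    "run_condition",
    "empirical_power",
    "relative_bias",
    "coverage95",
    "summarize_condition",
    "assemble_tables",
    "run_study",
]

METHODS = (
    "complete_sem",
    "mega_sem",
    "fs_meta",
    "ss_meta",
    "impute",
    "mega_no_panel",
    "fs_no_panel",
)

_COND_INDEX = {c: i for i, c in enumerate(datagen.SAMPLE_SIZE_CONDITIONS)}
_Z95 = 1.96


def default_groups() -> dict[str, list[str]]:
    return {
        "Q1": datagen.ITEM_COLUMNS[:4],
        "Q2": datagen.ITEM_COLUMNS[4:],
    }


def analysis_pairs(spec: datagen.GeneratingModelSpec) -> list[tuple[str, str]]:
    """The fitted BFIM frees the residual covariance of the known
    similarly-worded bridge pair (the same a-priori knowledge the no-panel
    design uses to merge them)."""
    i, j = spec.bridge_pair
    return [(datagen.ITEM_COLUMNS[i], datagen.ITEM_COLUMNS[j])]


def no_panel_groups(spec: datagen.GeneratingModelSpec) -> dict[str, list[str]]:
    cols = datagen.no_panel_item_columns(spec)
    i, _ = spec.bridge_pair
    # merged item joins the questionnaire-1 factor (a choice forced by the
    # one-specific-factor-per-item rule; symmetric by construction)
    return {"Q1": cols[: i + 1], "Q2": cols[i + 1 :]}


@dataclass
class ConditionResult:
    """Per-replication records for one grid cell (and one effect/null state)."""

    model_id: int
    condition_id: str
    null: bool
    n_reps: int
    base_seed: int
    true_gamma: float
    records: pd.DataFrame  # rep, method, beta, se, p, ci_low, ci_high, converged
    spec_overrides: dict | None = None


def _rep_rng(base_seed, model_id, condition_id, rep, null, tag):
    ss = np.random.SeedSequence(
        [int(base_seed), int(model_id), _COND_INDEX[condition_id], int(rep),
         int(null), int(tag)]
    )
    return np.random.default_rng(ss)


def _record(method, rep, beta=np.nan, se=np.nan, p=np.nan, converged=False):
    ci_low = beta - _Z95 * se
    ci_high = beta + _Z95 * se
    return {
        "rep": rep,
        "method": method,
        "beta": beta,
        "se": se,
        "p": p,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "converged": bool(converged),
    }


def _sem_arm(df, spec, method, rep):
    model = BiFactorModel(df, spec)
    res = model.fit()
    beta, se, _, p = res.wald_gamma("snp")
    ok = res.converged and np.isfinite(se) and se > 0
    if not ok:
        return _record(method, rep, beta=beta, converged=False)
    return _record(method, rep, beta, se, p, converged=True)


def _studies_present(df):
    return [s for s in ("cohort1", "cohort2", "ref") if (df["cohort"] == s).any()]


def _meta_arm(df, outcome, method, rep, kind):
    results = []
    for study in _studies_present(df):
        sub = df["cohort"] == study
        results.append(
            ols_assoc(outcome[sub], df.loc[sub, "snp"], df.loc[sub, "sex"],
                      outcome_kind=kind, study=study)
        )
    meta = fixed_effects_meta(results)
    return _record(method, rep, meta.beta, meta.se, meta.p, converged=True)


def _fs_arm(df, spec, method, rep):
    model = BiFactorModel(df, spec)
    res = model.fit(compute_se=False)
    if not res.converged:
        return _record(method, rep, converged=False)
    scores = res.factor_scores()
    return _meta_arm(df, scores["T"].to_numpy(), method, rep, "factor_score")


def apply_spec_overrides(
    spec: datagen.GeneratingModelSpec, overrides: dict
) -> datagen.GeneratingModelSpec:
    """Sensitivity-run overrides of generating-model constants (e.g.
    ``bridge_rho``, ``gamma_snp``, ``gamma_sex``, ``maf``).  When a
    structural coefficient or the allele frequency changes and no explicit
    disturbance variance is supplied, ``zeta_var`` is re-solved to keep the
    marginal trait variance at 1."""
    import dataclasses

    overrides = dict(overrides)
    if {"gamma_snp", "gamma_sex", "maf"} & overrides.keys() and (
        "zeta_var" not in overrides
    ):
        g_snp = overrides.get("gamma_snp", spec.gamma_snp)
        g_sex = overrides.get("gamma_sex", spec.gamma_sex)
        maf = overrides.get("maf", spec.maf)
        var_snp = 2.0 * maf * (1.0 - maf)
        overrides["zeta_var"] = 1.0 - g_snp**2 * var_snp - g_sex**2 * 0.25
    return dataclasses.replace(spec, **overrides)


def run_condition(
    model_id: int,
    condition_id: str,
    methods=("complete_sem", "mega_sem", "fs_meta", "ss_meta"),
    n_reps: int = 200,
    base_seed: int = 0,
    null: bool = False,
    impute_config: ImputationConfig | None = None,
    impute_reps: int | None = None,
    spec_overrides: dict | None = None,
) -> ConditionResult:
    """Run one grid cell for the requested arms.

    ``impute_reps`` caps the (expensive) imputation arm at the first so-many
    replications; other arms always run all ``n_reps``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    spec = datagen.build_generating_model(model_id, null_snp=null)
    if spec_overrides:
        spec = apply_spec_overrides(spec, spec_overrides)
    sizes = datagen.SAMPLE_SIZE_CONDITIONS[condition_id]
    impute_config = impute_config or ImputationConfig()
    if impute_reps is None:
        impute_reps = n_reps
    groups = default_groups()
    pairs = analysis_pairs(spec)
    sem_spec = BiFactorSpec.from_groups(groups, ("snp", "sex"), pairs)
    # the factor-score model leaves the genetic variant out but keeps sex:
    # the sex-item covariances anchor the general/specific split that the
    # small reference panel alone identifies only weakly
    meas_spec = BiFactorSpec.from_groups(groups, ("sex",), pairs)
    np_groups = no_panel_groups(spec)
    np_sem_spec = BiFactorSpec.from_groups(np_groups, ("snp", "sex"))
    np_meas_spec = BiFactorSpec.from_groups(np_groups, ("sex",))

    rows = []
    need_panel_data = bool(
        {"complete_sem", "mega_sem", "fs_meta", "ss_meta", "impute"} & set(methods)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for rep in range(n_reps):
            if need_panel_data:
                rng = _rep_rng(base_seed, model_id, condition_id, rep, null, 0)
                complete = datagen.simulate_complete(spec, sizes, rng)
                masked = datagen.apply_missing_by_design(complete)
            for method in methods:
                try:
                    if method == "complete_sem":
                        rows.append(_sem_arm(complete, sem_spec, method, rep))
                    elif method == "mega_sem":
                        rows.append(_sem_arm(masked, sem_spec, method, rep))
                    elif method == "fs_meta":
                        rows.append(_fs_arm(masked, meas_spec, method, rep))
                    elif method == "ss_meta":
                        outcome = sum_score(masked, datagen.ITEM_COLUMNS).to_numpy()
                        rows.append(_meta_arm(masked, outcome, method, rep, "sum_score"))
                    elif method == "impute":
                        if rep >= impute_reps:
                            continue
                        i_rng = _rep_rng(base_seed, model_id, condition_id, rep, null, 2)
                        res = impute_mega_analysis(
                            masked, datagen.ITEM_COLUMNS, impute_config, i_rng
                        )
                        rows.append(
                            _record(method, rep, res.beta, res.se, res.p, True)
                        )
                    elif method in ("mega_no_panel", "fs_no_panel"):
                        n_rng = _rep_rng(base_seed, model_id, condition_id, rep, null, 1)
                        df_np = datagen.make_no_panel_dataset(spec, sizes, n_rng)
                        if method == "mega_no_panel":
                            rows.append(_sem_arm(df_np, np_sem_spec, method, rep))
                        else:
                            rows.append(_fs_arm(df_np, np_meas_spec, method, rep))
                except Exception:
                    rows.append(_record(method, rep, converged=False))
    records = pd.DataFrame(
        rows,
        columns=["rep", "method", "beta", "se", "p", "ci_low", "ci_high", "converged"],
    )
    return ConditionResult(
        model_id=model_id,
        condition_id=condition_id,
        null=null,
        n_reps=n_reps,
        base_seed=base_seed,
        true_gamma=spec.gamma_snp,
        records=records,
        spec_overrides=spec_overrides,
    )


# ----------------------------------------------------------------------
# arm-specific population coefficients (bias/coverage reference values)
# ----------------------------------------------------------------------

def _observed_sets(sizes: datagen.SampleSizeCondition, no_panel: bool = False):
    """(observed item index set, study size) per study contributing to a
    meta-analysis arm."""
    q1, q2 = list(range(4)), list(range(4, 8))
    if no_panel:
        s = datagen._reallocate_no_panel(sizes)
        return [(q1, s.n_cohort1), (q2, s.n_cohort2)]
    out = [(q1, sizes.n_cohort1), (q2, sizes.n_cohort2)]
    if sizes.n_ref:
        out.append((list(range(8)), sizes.n_ref))
    return out


def _pooled_truth(gen_spec, observed_sets, weight_fn):
    """Inverse-variance (population) pooled true SNP coefficient across
    studies, for an outcome defined by per-study weight vectors w:
    beta_s = w' Cov(y_O, snp) / Var(snp) = (w' efflam_O) gamma."""
    sigma = gen_spec.implied_item_cov()
    eff = gen_spec.effective_general_loadings()
    var_snp = 2.0 * gen_spec.maf * (1.0 - gen_spec.maf)
    betas, weights = [], []
    for obs, n_s in observed_sets:
        obs = np.asarray(obs)
        w = weight_fn(sigma[np.ix_(obs, obs)], eff[obs])
        beta = float(w @ eff[obs]) * gen_spec.gamma_snp
        beta_sex = float(w @ eff[obs]) * gen_spec.gamma_sex
        var_out = float(w @ sigma[np.ix_(obs, obs)] @ w)
        resid = var_out - beta**2 * var_snp - beta_sex**2 * 0.25
        betas.append(beta)
        weights.append(n_s / max(resid, 1e-12))
    betas, weights = np.asarray(betas), np.asarray(weights)
    return float(np.sum(weights * betas) / np.sum(weights))


def arm_true_beta(
    gen_spec: datagen.GeneratingModelSpec,
    sizes: datagen.SampleSizeCondition,
    method: str,
) -> float:
    """The population regression coefficient each arm estimates.

    The latent-trait arms target gamma_SNP itself.  The manifest-score arms
    target the population coefficient of their outcome on the SNP: the mean
    of available items (sum-score meta), the true-parameter regression
    factor score (factor-score meta), or the complete item sum (imputation
    mega-analysis), pooled across studies with population inverse-variance
    weights.
    """
    if method in ("complete_sem", "mega_sem", "mega_no_panel"):
        return gen_spec.gamma_snp
    if method == "impute":
        eff = gen_spec.effective_general_loadings()
        return float(eff.sum()) * gen_spec.gamma_snp
    if method in ("ss_meta", "fs_meta", "fs_no_panel"):
        no_panel = method == "fs_no_panel"
        if method == "ss_meta":
            weight_fn = lambda sig, lam: np.full(len(lam), 1.0 / len(lam))
        else:
            weight_fn = lambda sig, lam: np.linalg.solve(sig, lam)
        return _pooled_truth(gen_spec, _observed_sets(sizes, no_panel), weight_fn)
    raise ValueError(f"unknown method {method!r}")


# ----------------------------------------------------------------------
# outcome metrics
# ----------------------------------------------------------------------

def empirical_power(p_values, alpha: float = 0.05) -> float:
    """Proportion of replications with p below alpha."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    return float(np.mean(p < alpha))


def relative_bias(estimates, true_value: float) -> float:
    """(mean estimate - true) / true."""
    if true_value == 0:
        raise ValueError("relative bias is undefined for a zero true value; "
                         "report absolute bias for null runs")
    est = np.asarray(estimates, float)
    return float((est.mean() - true_value) / true_value)


def coverage95(ci_low, ci_high, true_value: float) -> float:
    """Proportion of intervals containing the true value."""
    lo = np.asarray(ci_low, float)
    hi = np.asarray(ci_high, float)
    if lo.size == 0:
        raise ValueError("no intervals supplied")
    if np.any(hi < lo):
        raise ValueError("interval bounds must be ordered")
    return float(np.mean((lo <= true_value) & (true_value <= hi)))


def summarize_condition(
    effect: ConditionResult, null: ConditionResult | None = None
) -> pd.DataFrame:
    """Per-method power, bias, coverage (effect run) and type-I error (null
    run), over converged replications; non-convergence is reported via
    ``convergence_rate`` and flagged unreliable below 50%."""
    rows = []
    gen_spec = datagen.build_generating_model(effect.model_id)
    if effect.spec_overrides:
        gen_spec = apply_spec_overrides(gen_spec, effect.spec_overrides)
    sizes = datagen.SAMPLE_SIZE_CONDITIONS[effect.condition_id]
    for method, grp in effect.records.groupby("method", sort=False):
        true = arm_true_beta(gen_spec, sizes, method)
        conv = grp[grp["converged"]]
        n_attempted = len(grp)
        rate = len(conv) / n_attempted if n_attempted else 0.0
        row = {
            "model": effect.model_id,
            "condition": effect.condition_id,
            "method": method,
            "n_reps": n_attempted,
            "convergence_rate": rate,
            "reliable": rate >= 0.5,
            "power": np.nan,
            "relative_bias": np.nan,
            "coverage95": np.nan,
            "type1": np.nan,
        }
        if len(conv):
            row["power"] = empirical_power(conv["p"])
            row["relative_bias"] = relative_bias(conv["beta"], true)
            row["coverage95"] = coverage95(conv["ci_low"], conv["ci_high"], true)
        if null is not None:
            ngrp = null.records[
                (null.records["method"] == method) & null.records["converged"]
            ]
            if len(ngrp):
                row["type1"] = empirical_power(ngrp["p"])
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# study driver and result tables
# ----------------------------------------------------------------------

_TABLE2_POWER = {
    "complete_sem": "complete_data_power",
    "mega_sem": "mega_sem_power",
    "fs_meta": "fs_meta_power",
    "ss_meta": "ss_meta_power",
    "impute": "impute_power",
}
_TABLE2_T1 = {
    "complete_sem": "full_t1",
    "mega_sem": "mega_t1",
    "fs_meta": "fs_t1",
    "ss_meta": "ss_t1",
    "impute": "impute_t1",
}
_TABLE3_BIAS = {
    "mega_sem": "mega_bias",
    "fs_meta": "fs_bias",
    "ss_meta": "ss_bias",
    "impute": "impute_bias",
}
_TABLE3_COV = {
    "mega_sem": "mega_coverage",
    "fs_meta": "fs_coverage",
    "ss_meta": "ss_coverage",
    "impute": "impute_coverage",
}


def assemble_tables(summaries: list[pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Reshape per-condition summaries into the three study tables:
    power + type-I error, bias + coverage, and the no-panel table (relative
    power against the complete-data benchmark, plus bias)."""
    if not summaries:
        raise ValueError("no condition summaries supplied")
    long = pd.concat(summaries, ignore_index=True)
    t2_rows, t3_rows, t4_rows = [], [], []
    for (model, cond), grp in long.groupby(["model", "condition"], sort=True):
        by = {r["method"]: r for _, r in grp.iterrows()}
        t2 = {"model": model, "condition": cond}
        for m, col in _TABLE2_POWER.items():
            t2[col] = by[m]["power"] if m in by else np.nan
        for m, col in _TABLE2_T1.items():
            t2[col] = by[m]["type1"] if m in by else np.nan
        t2_rows.append(t2)
        t3 = {"model": model, "condition": cond}
        for m, col in _TABLE3_BIAS.items():
            t3[col] = by[m]["relative_bias"] if m in by else np.nan
        for m, col in _TABLE3_COV.items():
            t3[col] = by[m]["coverage95"] if m in by else np.nan
        t3_rows.append(t3)
        if {"mega_no_panel", "fs_no_panel"} & by.keys():
            bench = by.get("complete_sem", {}).get("power", np.nan)
            t4 = {"model": model, "condition": cond}
            for m, prefix in (("mega_no_panel", "mega"), ("fs_no_panel", "fs")):
                if m in by:
                    t4[f"{prefix}_rel_power"] = (
                        by[m]["power"] / bench if bench and np.isfinite(bench) else np.nan
                    )
                    t4[f"{prefix}_bias"] = by[m]["relative_bias"]
                    t4[f"{prefix}_convergence"] = by[m]["convergence_rate"]
            t4_rows.append(t4)
    tables = {
        "table2": pd.DataFrame(t2_rows),
        "table3": pd.DataFrame(t3_rows),
    }
    tables["table4_nopanel"] = pd.DataFrame(t4_rows)
    return tables


def run_study(
    models=(1, 2, 3, 4),
    conditions=("N1", "N2", "N3", "N4", "N5"),
    methods=("complete_sem", "mega_sem", "fs_meta", "ss_meta"),
    n_reps: int = 200,
    base_seed: int = 0,
    with_null: bool = True,
    impute_config: ImputationConfig | None = None,
    impute_reps: int | None = None,
    spec_overrides: dict | None = None,
) -> dict[str, object]:
    """Run the full grid; returns summaries, tables and raw condition results."""
    summaries, raw = [], []
    for model_id in models:
        for cond in conditions:
            eff = run_condition(
                model_id, cond, methods, n_reps, base_seed,
                null=False, impute_config=impute_config, impute_reps=impute_reps,
                spec_overrides=spec_overrides,
            )
            nul = (
                run_condition(
                    model_id, cond, methods, n_reps, base_seed,
                    null=True, impute_config=impute_config, impute_reps=impute_reps,
                    spec_overrides=spec_overrides,
                )
                if with_null
                else None
            )
            summaries.append(summarize_condition(eff, nul))
            raw.append((eff, nul))
    return {
        "summaries": summaries,
        "tables": assemble_tables(summaries),
        "raw": raw,
    }
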