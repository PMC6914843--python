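"""FIML estimation: pattern handling, likelihood oracle, EM, scores, fit."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from bfim import datagen
from bfim.datagen import ITEM_COLUMNS, SampleSizeCondition
from bfim.estimate import (
    BiFactorModel,
    PatternPartition,
    baseline_fit,
    fiml_loglik,
    fit_bfim,
    fit_indices_from_chisq,
    partition_patterns,
    regression_factor_scores,
    saturated_fit,
)
from bfim.model import BiFactorSpec, ParameterSet, pack_parameters, unpack_parameters

GROUPS = {"Q1": ITEM_COLUMNS[:4], "Q2": ITEM_COLUMNS[4:]}
PAIRS = [("y4", "y5")]


def naive_rowwise_loglik(params, y, x=None):
    """Brute-force FIML: one multivariate-normal density per row, no
    caching, assembled from the conditional implied moments."""
    from bfim.model import implied_covariance, implied_mean

    total = 0.0
    for j in range(y.shape[0]):
        obs = np.flatnonzero(~np.isnan(y[j]))
        sigma = implied_covariance(params, obs, conditional=True)
        mu = implied_mean(params, None if x is None else x[j], obs)
        total += stats.multivariate_normal.logpdf(y[j, obs], mean=mu, cov=sigma)
    return total


class TestPatternPartition:
    def test_panel_design_has_three_patterns(self, toy_masked):
        part = partition_patterns(toy_masked, ITEM_COLUMNS)
        assert len(part) == 3
        assert sum(p.rows.size for p in part.patterns) == len(toy_masked)

    def test_complete_data_single_pattern(self, toy_complete):
        part = partition_patterns(toy_complete, ITEM_COLUMNS)
        assert len(part) == 1

    def test_merged_bridge_design_two_patterns(self, model1_spec):
        df = make = datagen.make_no_panel_dataset(
            model1_spec, datagen.SAMPLE_SIZE_CONDITIONS["N2"], np.random.default_rng(0)
        )
        cols = datagen.no_panel_item_columns(model1_spec)
        part = partition_patterns(df, cols)
        assert len(part) == 2
        assert part.n_items == 7

    def test_empty_rows_excluded_with_warning(self):
        y = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, np.nan]])
        with pytest.warns(UserWarning, match="no observed items"):
            part = PatternPartition(y)
        assert part.n_rows == 2
        assert part.n_dropped == 1


class TestFimlLoglik:
    def _params(self):
        spec = BiFactorSpec.from_groups(GROUPS, ("snp", "sex"), PAIRS)
        rng = np.random.default_rng(8)
        vec = np.concatenate(
            [
                rng.normal(scale=0.2, size=8),
                rng.uniform(0.3, 0.7, 16),
                rng.uniform(0.2, 0.8, 8),
                np.array([0.05, 0.8]),
                np.array([0.15]),
            ]
        )
        return unpack_parameters(vec, spec, np.diag([0.5, 0.25]))

    def test_agrees_with_naive_per_row_oracle(self, model1_spec):
        df = datagen.generate_dataset(
            model1_spec, SampleSizeCondition("tiny", 20, 20, 10),
            np.random.default_rng(3),
        )
        params = self._params()
        y = df[ITEM_COLUMNS].to_numpy(float)
        x = df[["snp", "sex"]].to_numpy(float)
        part = PatternPartition(y, x)
        fast = fiml_loglik(params, part, np.diag([0.5, 0.25]))
        slow = naive_rowwise_loglik(params, y, x)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_invariant_to_row_permutation(self, model1_spec):
        df = datagen.generate_dataset(
            model1_spec, SampleSizeCondition("tiny", 30, 30, 15),
            np.random.default_rng(4),
        )
        params = self._params()
        y = df[ITEM_COLUMNS].to_numpy(float)
        x = df[["snp", "sex"]].to_numpy(float)
        ll1 = fiml_loglik(params, PatternPartition(y, x))
        perm = np.random.default_rng(0).permutation(len(y))
        ll2 = fiml_loglik(params, PatternPartition(y[perm], x[perm]))
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_complete_data_equals_direct_mvn(self, toy_complete):
        spec = BiFactorSpec.from_groups(GROUPS, (), PAIRS)
        rng = np.random.default_rng(9)
        vec = np.concatenate(
            [rng.normal(scale=0.2, size=8), rng.uniform(0.3, 0.7, 16),
             rng.uniform(0.2, 0.8, 8), np.array([0.1])]
        )
        params = unpack_parameters(vec, spec)
        y = toy_complete[ITEM_COLUMNS].to_numpy(float)
        from bfim.model import implied_covariance

        direct = stats.multivariate_normal.logpdf(
            y, mean=params.nu, cov=implied_covariance(params)
        ).sum()
        assert fiml_loglik(params, PatternPartition(y)) == pytest.approx(
            direct, rel=1e-12
        )

    def test_analytic_score_matches_numeric_gradient(self, toy_masked):
        model = BiFactorModel(
            toy_masked, BiFactorSpec.from_groups(GROUPS, ("snp", "sex"), PAIRS)
        )
        x0 = model.start_params() + 0.02 * np.random.default_rng(1).normal(
            size=model.spec.n_free
        )
        g = model.score(x0)
        num = optimize.approx_fprime(x0, model.loglike, 1e-7)
        np.testing.assert_allclose(g, num, rtol=5e-4, atol=5e-3)


class TestFit:
    def test_loglik_never_below_start(self, toy_masked):
        model = BiFactorModel(
            toy_masked, BiFactorSpec.from_groups(GROUPS, ("snp", "sex"), PAIRS)
        )
        res = model.fit()
        assert res.llf >= model.loglike(model.start_params())
        assert res.converged
        assert res.gradient_norm < 1e-4

    def test_se_in_packing_order_blocks(self, toy_masked):
        res = fit_bfim(
            toy_masked, BiFactorSpec.from_groups(GROUPS, ("snp", "sex"), PAIRS)
        )
        assert res.se_for("gamma").shape == (2,)
        assert np.all(res.se_for("gamma") > 0)
        est, se, z, p = res.wald_gamma("snp")
        assert z == pytest.approx(est / se)
        assert 0 < p <= 1

    def test_summary_mentions_structural_block(self, toy_masked):
        res = fit_bfim(
            toy_masked, BiFactorSpec.from_groups(GROUPS, ("snp", "sex"), PAIRS)
        )
        text = res.summary()
        assert "psi_zeta" in text and "snp" in text

    def test_missing_columns_rejected(self, toy_masked):
        spec = BiFactorSpec(("nope", "y2"), (0, 0))
        with pytest.raises(KeyError):
            BiFactorModel(toy_masked, spec)


class TestSaturatedFit:
    def test_complete_data_fixed_point_is_sample_moments(self, toy_complete):
        y = toy_complete[ITEM_COLUMNS].to_numpy(float)
        part = PatternPartition(y)
        mu, sigma, ll = saturated_fit(part)
        np.testing.assert_allclose(mu, y.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(sigma, np.cov(y, rowvar=False, ddof=0), atol=1e-8)

    def test_saturated_loglik_dominates_structured_model(self, toy_masked):
        part = partition_patterns(toy_masked, ITEM_COLUMNS)
        _, _, ll_sat = saturated_fit(part)
        res = fit_bfim(toy_masked, BiFactorSpec.from_groups(GROUPS, (), PAIRS))
        assert ll_sat >= res.llf

    def test_two_pattern_toy_against_direct_ml(self):
        # 2 items, 6 rows, one row missing item 2: EM solution must equal
        # the direct numerical maximizer of the observed-data likelihood
        y = np.array(
            [[0.2, 1.1], [-0.5, 0.3], [1.4, 2.0], [0.1, np.nan], [-1.2, np.nan],
             [0.7, 0.9]]
        )
        part = PatternPartition(y)
        mu, sigma, ll = saturated_fit(part, tol=1e-12)

        def negll(v):
            m = v[:2]
            s = np.array([[v[2], v[3]], [v[3], v[4]]])
            if np.linalg.eigvalsh(s)[0] <= 1e-8:
                return 1e9
            total = 0.0
            for row in y:
                obs = np.flatnonzero(~np.isnan(row))
                total += stats.multivariate_normal.logpdf(
                    row[obs], mean=m[obs], cov=s[np.ix_(obs, obs)]
                )
            return -total

        x0 = np.array([0.0, 0.0, 1.0, 0.1, 1.0])
        opt = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
        np.testing.assert_allclose(mu, opt.x[:2], atol=1e-5)
        np.testing.assert_allclose(
            [sigma[0, 0], sigma[0, 1], sigma[1, 1]], opt.x[2:], atol=1e-4
        )
        assert ll == pytest.approx(-opt.fun, abs=1e-8)


class TestFitIndices:
    def test_saturated_model_is_perfect(self):
        out = fit_indices_from_chisq(0.0, 12, 1000, 300.0, 28)
        assert out["rmsea"] == 0.0
        assert out["cfi"] == 1.0

    def test_chi2_equal_df_gives_zero_rmsea(self):
        out = fit_indices_from_chisq(40.0, 40, 500, 300.0, 56)
        assert out["rmsea"] == 0.0

    def test_hand_computed_toy(self):
        out = fit_indices_from_chisq(50.0, 40, 1000, 500.0, 56)
        assert out["rmsea"] == pytest.approx(np.sqrt(10.0 / 40000.0), abs=1e-6)
        assert out["cfi"] == pytest.approx(1.0 - 10.0 / 444.0, abs=1e-5)
        assert out["tli"] == pytest.approx(
            (500 / 56 - 50 / 40) / (500 / 56 - 1), abs=1e-6
        )

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            fit_indices_from_chisq(10.0, 0, 100, 50.0, 10)

    def test_fit_measures_on_wellspecified_model(self, toy_masked):
        res = fit_bfim(toy_masked, BiFactorSpec.from_groups(GROUPS, (), PAIRS))
        out = res.fit_measures()
        assert out["df"] == 44 - 33
        assert out["rmsea"] < 0.05  # correctly specified generating model
        assert out["cfi"] > 0.95

    def test_fit_measures_require_measurement_only(self, toy_masked):
        res = fit_bfim(
            toy_masked, BiFactorSpec.from_groups(GROUPS, ("snp", "sex"), PAIRS)
        )
        with pytest.raises(ValueError):
            res.fit_measures()


class TestFactorScores:
    def test_prior_mean_when_items_at_intercepts(self):
        spec = BiFactorSpec(("a", "b", "c", "d"), (0, 0, 1, 1))
        params = ParameterSet(
            np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 0.5), np.full(4, 0.4),
            np.full(4, 0.5), np.array([]), 1.0, spec,
        )
        y = np.array([[1.0, 2.0, 3.0, 4.0]])
        out = regression_factor_scores(params, y)
        np.testing.assert_allclose(out[["T", "eta1", "eta2"]].to_numpy(), 0.0,
                                   atol=1e-12)

    def test_single_item_closed_form(self):
        # lambda = 0.5, theta = 0.75, lambda_s = 0: T-hat = 0.5/(0.25+0.75)
        spec = BiFactorSpec(("a", "b"), (0, 0))
        params = ParameterSet(
            np.zeros(2), np.array([0.5, 0.5]), np.zeros(2), np.array([0.75, 0.75]),
            np.array([]), 1.0, spec,
        )
        y = np.array([[1.0, np.nan]])
        out = regression_factor_scores(params, y)
        assert out.loc[0, "T"] == pytest.approx(0.5, abs=1e-12)
        assert out.loc[0, "n_observed_items"] == 1

    def test_no_observed_items_flagged_with_prior_mean(self):
        spec = BiFactorSpec(("a", "b"), (0, 0))
        params = ParameterSet(
            np.zeros(2), np.full(2, 0.5), np.zeros(2), np.full(2, 0.75),
            np.array([]), 1.0, spec,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = regression_factor_scores(params, np.array([[np.nan, np.nan]]))
        assert out.loc[0, "T"] == 0.0
        assert out.loc[0, "n_observed_items"] == 0

    def test_scores_shrink_toward_prior(self, toy_masked):
        res = fit_bfim(toy_masked, BiFactorSpec.from_groups(GROUPS, ("sex",), PAIRS),
                       compute_se=False)
        scores = res.factor_scores()
        assert scores["T"].var() <= 1.0

    def test_factor_scores_track_trait_better_than_sum_score(self):
        spec = datagen.build_generating_model(3)
        sizes = SampleSizeCondition("big", 4000, 4000, 800)
        df = datagen.generate_dataset(spec, sizes, np.random.default_rng(21),
                                      keep_latent=True)
        res = fit_bfim(df, BiFactorSpec.from_groups(GROUPS, ("sex",), PAIRS),
                       compute_se=False)
        scores = res.factor_scores()["T"].to_numpy()
        ss = df[ITEM_COLUMNS].mean(axis=1).to_numpy()
        t = df["T"].to_numpy()
        assert np.corrcoef(scores, t)[0, 1] > np.corrcoef(ss, t)[0, 1]


class TestNullCalibration:
    def test_wald_p_uniform_under_null(self):
        spec = datagen.build_generating_model(1, null_snp=True)
        sizes = SampleSizeCondition("mid", 1500, 1500, 300)
        mspec = BiFactorSpec.from_groups(GROUPS, ("snp", "sex"), PAIRS)
        ps = []
        for rep in range(60):
            df = datagen.generate_dataset(spec, sizes, np.random.default_rng(7000 + rep))
            res = fit_bfim(df, mspec)
            ps.append(res.wald_gamma("snp")[3])
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01
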