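"""Generating-model construction and simulated-data moment checks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bfim import datagen
from bfim.datagen import (
    SAMPLE_SIZE_CONDITIONS,
    ITEM_COLUMNS,
    SampleSizeCondition,
    build_generating_model,
    generate_dataset,
    generate_genotypes,
    make_no_panel_dataset,
    simulate_complete,
)


class TestGeneratingModels:
    def test_disturbance_variance_matches_variance_decomposition(self):
        # 0.0447^2 * 0.5 + 0.8944^2 * 0.25 + psi_zeta = 1  =>  psi_zeta = 0.799
        spec = build_generating_model(1)
        assert spec.zeta_var == pytest.approx(0.799, abs=5e-4)
        assert (
            spec.gamma_snp**2 * 0.5 + spec.gamma_sex**2 * 0.25 + spec.zeta_var
        ) == pytest.approx(1.0, abs=1e-12)

    def test_model1_loadings_from_variance_shares(self):
        spec = build_generating_model(1)
        assert spec.loadings_general[0] == pytest.approx(np.sqrt(0.255), abs=1e-10)
        assert spec.loadings_specific[0] == pytest.approx(np.sqrt(0.345), abs=1e-10)
        np.testing.assert_allclose(spec.residual_vars, 0.40)

    def test_null_snp_flag_zeroes_the_coefficient(self):
        spec = build_generating_model(1, null_snp=True)
        assert spec.gamma_snp == 0.0
        assert spec.zeta_var == pytest.approx(0.8, abs=1e-3)

    def test_model3_specific_factor_moments(self):
        spec = build_generating_model(3)
        np.testing.assert_allclose(spec.specific_means, [0.0, 1.0])
        np.testing.assert_allclose(spec.specific_vars, [1.0, 3.0])

    def test_model2_weak_items_keep_45_percent_communality(self):
        spec = build_generating_model(2)
        communality = spec.loadings_general[4:] ** 2 + spec.loadings_specific[4:] ** 2
        np.testing.assert_allclose(communality, 0.45, atol=1e-12)
        np.testing.assert_allclose(spec.residual_vars[4:], 0.55)

    def test_models_1_and_2_have_unit_item_variance(self):
        for mid in (1, 2):
            spec = build_generating_model(mid)
            np.testing.assert_allclose(np.diag(spec.implied_item_cov()), 1.0)

    def test_model4_has_unit_item_variance_by_construction(self):
        spec = build_generating_model(4)
        np.testing.assert_allclose(np.diag(spec.implied_item_cov()), 1.0, atol=1e-12)

    def test_unknown_model_id_rejected(self):
        with pytest.raises(ValueError, match="model_id"):
            build_generating_model(5)

    def test_invalid_bridge_correlation_rejected(self):
        spec = build_generating_model(1)
        with pytest.raises(ValueError, match="bridge"):
            dataclasses.replace(spec, bridge_rho=1.0)

    def test_sample_size_conditions(self):
        expected = {
            "N1": (5000, 5000, 400),
            "N2": (2500, 2500, 400),
            "N3": (7500, 7500, 400),
            "N4": (2500, 7500, 400),
            "N5": (4500, 4500, 1000),
        }
        for cid, (n1, n2, nref) in expected.items():
            cond = SAMPLE_SIZE_CONDITIONS[cid]
            assert (cond.n_cohort1, cond.n_cohort2, cond.n_ref) == (n1, n2, nref)


class TestGenotypes:
    def test_hardy_weinberg_frequencies_and_variance(self):
        rng = np.random.default_rng(7)
        g = generate_genotypes(200_000, 0.5, rng)
        freqs = np.bincount(g, minlength=3) / len(g)
        # HWE with p = 0.5: (0.25, 0.50, 0.25); MC SE ~ 1e-3
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=3.5e-3)
        assert g.var() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(g)) * 2)

    @pytest.mark.parametrize("maf", [0.0, 1.0, -0.1])
    def test_degenerate_maf_rejected(self, maf):
        with pytest.raises(ValueError):
            generate_genotypes(10, maf, np.random.default_rng(0))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_genotypes(0, 0.5, np.random.default_rng(0))


BIG = SampleSizeCondition("big", 150_000, 0, 0)


class TestSimulatedMoments:
    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    def test_empirical_covariance_matches_closed_form(self, model_id):
        spec = build_generating_model(model_id)
        df = simulate_complete(spec, BIG, np.random.default_rng(100 + model_id))
        items = df[ITEM_COLUMNS].to_numpy()
        emp = np.cov(items, rowvar=False)
        implied = spec.implied_item_cov()
        n = len(df)
        # MC standard error of each covariance entry
        se = np.sqrt(
            (np.outer(np.diag(implied), np.diag(implied)) + implied**2) / n
        )
        assert np.all(np.abs(emp - implied) < 3.5 * se)
        np.testing.assert_allclose(
            items.mean(axis=0), spec.implied_item_mean(), atol=4 * np.sqrt(3.0 / n)
        )

    def test_model1_signature_correlations(self):
        spec = build_generating_model(1)
        df = simulate_complete(spec, BIG, np.random.default_rng(11))
        c = np.corrcoef(df[ITEM_COLUMNS].to_numpy(), rowvar=False)
        tol = 3 * 1.0 / np.sqrt(len(df))
        assert c[0, 1] == pytest.approx(0.60, abs=3 * tol)  # same questionnaire
        assert c[0, 7] == pytest.approx(0.255, abs=3 * tol)  # general factor only
        assert c[3, 4] == pytest.approx(0.495, abs=3 * tol)  # bridge pair

    def test_trait_variance_is_one(self):
        spec = build_generating_model(1)
        df = simulate_complete(spec, BIG, np.random.default_rng(12), keep_latent=True)
        t = df["T"].to_numpy()
        assert t.var() == pytest.approx(1.0, abs=3 * np.sqrt(2.0 / len(t)))

    def test_null_run_trait_uncorrelated_with_snp(self):
        spec = build_generating_model(1, null_snp=True)
        df = simulate_complete(spec, BIG, np.random.default_rng(13), keep_latent=True)
        r = np.corrcoef(df["snp"], df["T"])[0, 1]
        assert abs(r) < 3.5 / np.sqrt(len(df))


class TestDatasets:
    def test_missing_by_design_pattern(self, toy_masked):
        c1 = toy_masked[toy_masked["cohort"] == "cohort1"]
        c2 = toy_masked[toy_masked["cohort"] == "cohort2"]
        ref = toy_masked[toy_masked["cohort"] == "ref"]
        assert c1[ITEM_COLUMNS[:4]].notna().all().all()
        assert c1[ITEM_COLUMNS[4:]].isna().all().all()
        assert c2[ITEM_COLUMNS[4:]].notna().all().all()
        assert c2[ITEM_COLUMNS[:4]].isna().all().all()
        assert ref[ITEM_COLUMNS].notna().all().all()
        for col in ("snp", "sex", "cohort"):
            assert toy_masked[col].notna().all()

    def test_row_counts_conserved(self):
        spec = build_generating_model(1)
        for cid, cond in SAMPLE_SIZE_CONDITIONS.items():
            df = generate_dataset(spec, cond, np.random.default_rng(1))
            assert len(df) == cond.n_total

    def test_bit_identical_reproducibility(self, model1_spec):
        cond = SAMPLE_SIZE_CONDITIONS["N2"]
        a = generate_dataset(model1_spec, cond, np.random.default_rng(99))
        b = generate_dataset(model1_spec, cond, np.random.default_rng(99))
        pd.testing.assert_frame_equal(a, b)


class TestNoPanelDesign:
    def test_total_rows_conserved_with_no_ref(self, model1_spec):
        df = make_no_panel_dataset(
            model1_spec, SAMPLE_SIZE_CONDITIONS["N1"], np.random.default_rng(5)
        )
        assert len(df) == 10_400
        assert (df["cohort"] == "ref").sum() == 0
        assert (df["cohort"] == "cohort1").sum() == 5200

    def test_unbalanced_condition_adds_to_smaller_cohort(self, model1_spec):
        df = make_no_panel_dataset(
            model1_spec, SAMPLE_SIZE_CONDITIONS["N4"], np.random.default_rng(5)
        )
        assert (df["cohort"] == "cohort1").sum() == 2900
        assert (df["cohort"] == "cohort2").sum() == 7500

    def test_merged_bridge_column_fully_observed(self, model1_spec):
        df = make_no_panel_dataset(
            model1_spec, SAMPLE_SIZE_CONDITIONS["N2"], np.random.default_rng(5)
        )
        cols = datagen.no_panel_item_columns(model1_spec)
        assert len(cols) == 7
        assert df[datagen.BRIDGE_COLUMN].notna().all()
        # the six non-bridge items keep their cohort-specific missingness
        c1 = df[df["cohort"] == "cohort1"]
        assert c1[["y1", "y2", "y3"]].notna().all().all()
        assert c1[["y6", "y7", "y8"]].isna().all().all()
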