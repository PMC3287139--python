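import numpy as np
import pandas as pd
import pytest

import chemomir as cm


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_diff_features"):
            cm.SimulationConfig(n_features=10, n_diff_features=11)
        with pytest.raises(ValueError, match="noise_sd"):
            cm.SimulationConfig(noise_sd=0.0)
        with pytest.raises(ValueError, match=">= 0"):
            cm.SimulationConfig(n_pairs=-1)

    def test_default_rates_give_study_ttp(self):
        # no planted signal: exponential min, median ln2/(l0+lc) = 3.1 months
        c = cm.SimulationConfig(n_hazard_features=0)
        l0, lc = c.resolved_rates()
        total = l0 + lc
        assert np.isclose(np.log(2) / total, 3.1)
        assert np.isclose(lc / total, 0.2)

    def test_rate_calibration_accounts_for_planted_risk(self):
        # frailty spreads individual hazards; the calibrated rates must still
        # deliver the target observed median and censoring fraction
        cfg = cm.SimulationConfig(n_cancer=4000, n_features=30,
                                  n_diff_features=0, n_hazard_features=5,
                                  hazard_log_effect=1.0, seed=12)
        co = cm.generate_survival_cohort(cfg)
        assert abs(co.survival["ttp_months"].median() - 3.1) < 0.3
        assert abs(1.0 - co.survival["event"].mean() - 0.2) < 0.03


class TestCancerNormal:
    def test_same_seed_bit_identical(self):
        cfg = cm.SimulationConfig(n_features=40, n_cancer=10, n_normal=6,
                                  n_diff_features=4, n_hazard_features=0, seed=7)
        a = cm.generate_cancer_normal(cfg)
        b = cm.generate_cancer_normal(cfg)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_null_false_positive_rate(self):
        cfg = cm.SimulationConfig(n_features=1000, n_cancer=45, n_normal=17,
                                  diff_log2_effect=0.0, n_diff_features=0, seed=3)
        co = cm.generate_cancer_normal(cfg)
        tab = cm.t_test_per_feature(co.mirna_expression(), co.class_labels.to_numpy())
        rate = float((tab["p"] < 0.05).mean())
        # 99% binomial CI around 0.05 at m=1000
        half = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_planted_features_detectable(self):
        cfg = cm.SimulationConfig(n_features=1000, n_cancer=45, n_normal=17,
                                  n_diff_features=50, diff_log2_effect=1.0,
                                  noise_sd=0.5, seed=4)
        co = cm.generate_cancer_normal(cfg)
        tab = cm.t_test_per_feature(co.mirna_expression(), co.class_labels.to_numpy())
        planted = co.truth["feature_id"]
        frac = float((tab.loc[planted, "p"] < 0.005).mean())
        assert frac >= 0.90

    def test_effect_recovery_within_3_se(self):
        cfg = cm.SimulationConfig(n_features=200, n_cancer=60, n_normal=60,
                                  n_diff_features=20, diff_log2_effect=1.0,
                                  noise_sd=0.5, seed=5)
        co = cm.generate_cancer_normal(cfg)
        X = co.mirna_expression()
        diff = (X.iloc[:, :60].mean(axis=1) - X.iloc[:, 60:].mean(axis=1))
        for _, row in co.truth.iterrows():
            est = diff[row["feature_id"]]
            se = np.sqrt(2 * (0.5 ** 2 + 0.25 ** 2 / 4) / 60)
            assert abs(est - row["effect"]) < 3.5 * se


class TestSurvivalCohort:
    def test_uncensored_null_mean_matches_exponential(self):
        cfg = cm.SimulationConfig(n_cancer=5000, n_features=1, n_hazard_features=0,
                                  n_diff_features=0, censor_rate=0.0,
                                  baseline_hazard=0.25, seed=6)
        co = cm.generate_survival_cohort(cfg)
        assert co.survival["event"].all()
        mean = co.survival["ttp_months"].mean()
        assert abs(mean - 4.0) < 3 * 4.0 / np.sqrt(5000)

    def test_median_ttp_and_censoring_match_study(self):
        cfg = cm.SimulationConfig(n_cancer=4000, n_features=1, n_diff_features=0,
                                  n_hazard_features=0, seed=7)
        co = cm.generate_survival_cohort(cfg)
        assert abs(co.survival["ttp_months"].median() - 3.1) < 0.25
        assert abs(1.0 - co.survival["event"].mean() - 0.2) < 0.02

    def test_null_cox_type_i_error(self):
        cfg = cm.SimulationConfig(n_cancer=82, n_features=500,
                                  n_hazard_features=0, seed=8)
        co = cm.generate_survival_cohort(cfg)
        s = co.survival
        sel = cm.select_survival_features(co.mirna_expression(),
                                          s["ttp_months"], s["event"].astype(bool))
        rate = len(sel.selected) / 500
        half = 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_all_censored_warns(self):
        cfg = cm.SimulationConfig(n_cancer=20, n_features=5, n_diff_features=0,
                                  n_hazard_features=0,
                                  baseline_hazard=1e-6, censor_rate=5.0, seed=9)
        with pytest.warns(UserWarning, match="censored"):
            cm.generate_survival_cohort(cfg)

    def test_planted_block_is_coexpressed(self):
        cfg = cm.SimulationConfig(n_cancer=400, n_features=50, n_diff_features=0,
                                  n_hazard_features=4,
                                  hazard_factor_corr=0.5, seed=10)
        co = cm.generate_survival_cohort(cfg)
        X = co.mirna_expression()
        hz = co.truth.set_index("feature_id")["effect"]
        sub = X.loc[hz.index].mul(np.sign(hz), axis=0)
        corr = np.corrcoef(sub.to_numpy())
        off = corr[np.triu_indices(4, 1)]
        assert np.all(off > 0.3)  # sign-aligned block correlation near rho
        # marginal variance unchanged
        assert np.allclose(X.loc[hz.index].std(axis=1), 0.5, atol=0.12)


class TestPairs:
    @pytest.fixture(scope="class")
    def cohort_and_direction(self):
        cfg = cm.SimulationConfig(n_cancer=82, n_features=60, n_diff_features=0,
                                  n_hazard_features=4, n_pairs=8, seed=11)
        co = cm.generate_survival_cohort(cfg)
        hz = co.truth.set_index("feature_id")["effect"]
        return co, hz

    def test_zero_shift_zero_noise_identity(self, cohort_and_direction):
        co, direction = cohort_and_direction
        pc = cm.generate_pairs(co, direction, pair_shift=0.0, technical_sd=0.0)
        X = pc.mirna_expression()
        for _, row in pc.pairs.iterrows():
            assert np.allclose(X[row["pre"]], X[row["post"]])

    def test_positive_shift_moves_along_direction(self, cohort_and_direction):
        co, direction = cohort_and_direction
        pc = cm.generate_pairs(co, direction, pair_shift=2.0, technical_sd=0.0)
        X = pc.mirna_expression()
        unit = direction.reindex(X.index).fillna(0.0).to_numpy()
        unit = unit / np.linalg.norm(unit)
        for _, row in pc.pairs.iterrows():
            delta = (X[row["post"]] - X[row["pre"]]).to_numpy()
            assert np.allclose(delta, 2.0 * unit, atol=1e-10)

    def test_pre_samples_are_low_risk(self, cohort_and_direction):
        co, direction = cohort_and_direction
        pc = cm.generate_pairs(co, direction, technical_sd=0.0)
        X = pc.mirna_expression()
        hz = co.truth.set_index("feature_id")["effect"]
        for _, row in pc.pairs.iterrows():
            latent = float(hz @ X.loc[hz.index, row["pre"]])
            assert latent < 0.0

    def test_zero_direction_raises(self, cohort_and_direction):
        co, _ = cohort_and_direction
        with pytest.raises(ValueError, match="zero"):
            cm.generate_pairs(co, pd.Series(0.0, index=["syn-miR-0001"]))

    def test_clinical_table_pairs_validate(self, cohort_and_direction, tmp_path):
        co, direction = cohort_and_direction
        pc = cm.generate_pairs(co, direction)
        path = tmp_path / "clin.tsv"
        cm.write_clinical_tsv(pc.clinical_table(), path)
        back = cm.read_clinical_tsv(path)  # raises on invalid pairing
        assert (back["pair_id"] != "").sum() == 16
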