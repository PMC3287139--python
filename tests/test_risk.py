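import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

import chemomir as cm
from chemomir.risk import RiskModel


class TestRiskModelIdentities:
    def test_weights_reproduce_two_step_pc_computation(self, fitted_risk_model,
                                                        planted_survival_data):
        model = fitted_risk_model
        X, _, _ = planted_survival_data
        sub = X.loc[model.selected_features].to_numpy().T
        scores = (sub - model.means) @ model.loadings
        pi_two_step = scores @ model.pc_betas
        pi_weights = (sub - model.means) @ model.weights
        assert np.max(np.abs(pi_two_step - pi_weights)) < 1e-10
        assert np.max(np.abs(pi_weights - model.training_pi)) < 1e-10

    def test_loadings_orthonormal(self, fitted_risk_model):
        L = fitted_risk_model.loadings
        assert abs(L[:, 0] @ L[:, 1]) < 1e-10
        assert np.allclose(np.linalg.norm(L, axis=0), 1.0, atol=1e-10)

    def test_loading_sign_flip_leaves_pi_unchanged(self, fitted_risk_model,
                                                    planted_survival_data):
        m = fitted_risk_model
        X, _, _ = planted_survival_data
        flipped = RiskModel(
            selected_features=m.selected_features, means=m.means,
            loadings=m.loadings * np.array([-1.0, 1.0]),
            pc_betas=m.pc_betas * np.array([-1.0, 1.0]),
            weights=(m.loadings * np.array([-1.0, 1.0])) @ (m.pc_betas * np.array([-1.0, 1.0])),
            training_pi=m.training_pi, cutoff_percentile=m.cutoff_percentile)
        for s in X.columns[:10]:
            assert np.isclose(cm.predict_pi(m, X[s]), cm.predict_pi(flipped, X[s]),
                              atol=1e-10)

    def test_sample_at_training_means_scores_zero(self, fitted_risk_model):
        m = fitted_risk_model
        x = pd.Series(m.means, index=m.selected_features)
        assert cm.predict_pi(m, x) == 0.0

    def test_degenerate_pca_reduces_to_single_feature(self):
        # variance concentrated on feature 1: PI proportional to b1*(x1 - m1)
        rng = np.random.default_rng(3)
        n = 40
        x1 = rng.normal(0, 2.0, n)
        x2 = rng.normal(0, 0.05, n)
        t = np.exp(-0.8 * x1) * rng.exponential(1.0, n)
        e = np.ones(n, dtype=bool)
        X = pd.DataFrame([x1, x2], index=["f1", "f2"],
                         columns=[f"s{i}" for i in range(n)])
        model = cm.fit_risk_model(X, t, e, selection_alpha=0.9999)
        # the first loading collapses onto feature 1 ...
        assert abs(model.loadings[0, 0]) > 0.999
        # ... so the PI is essentially b1*(x1 - m1)
        pi = model.training_pi
        centered = x1 - x1.mean()
        r = np.corrcoef(pi, centered)[0, 1]
        assert abs(r) > 0.99
        b1 = model.pc_betas[0] * model.loadings[0, 0]
        assert np.allclose(pi, b1 * centered, atol=0.2 * np.std(pi))

    def test_monotone_in_weight_direction(self, fitted_risk_model):
        m = fitted_risk_model
        x = pd.Series(m.means + 0.1, index=m.selected_features)
        base = cm.predict_pi(m, x)
        c = 0.7
        bumped = x + c * pd.Series(m.weights, index=m.selected_features)
        assert np.isclose(cm.predict_pi(m, bumped) - base,
                          c * float(m.weights @ m.weights), atol=1e-10)

    def test_missing_feature_raises(self, fitted_risk_model):
        m = fitted_risk_model
        x = pd.Series(m.means[:-1], index=m.selected_features[:-1])
        with pytest.raises(ValueError, match="lacks selected feature"):
            cm.predict_pi(m, x)

    def test_too_few_selected_features_raises(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 30)),
                         index=[f"f{i}" for i in range(5)],
                         columns=[f"s{i}" for i in range(30)])
        t = rng.exponential(size=30)
        e = np.ones(30, dtype=bool)
        with pytest.raises(ValueError, match="selection_alpha"):
            cm.fit_risk_model(X, t, e, selection_alpha=1e-9)

    def test_save_load_round_trip(self, fitted_risk_model, tmp_path):
        p = tmp_path / "model.json"
        cm.save_model(fitted_risk_model, p)
        back = cm.load_model(p)
        assert back.selected_features == fitted_risk_model.selected_features
        assert np.allclose(back.weights, fitted_risk_model.weights)
        assert np.allclose(back.training_pi, fitted_risk_model.training_pi)


class TestPercentileAndGroups:
    def test_counting_rule(self):
        train = np.array([1.0, 2.0, 3.0, 4.0])
        assert cm.pi_percentile(train, 2.5) == 50.0
        assert cm.pi_percentile(train, 0.0) == 0.0
        assert cm.pi_percentile(train, 9.0) == 100.0

    def test_training_median_maps_to_50(self):
        train = np.array([5.0, 1.0, 3.0, 2.0, 4.0])  # odd n
        assert cm.pi_percentile(train, 3.0) == 50.0

    @pytest.mark.parametrize("pct,group", [
        (39.0, "low"), (67.0, "low"), (67.01, "high"), (100.0, "high"), (0.0, "low"),
    ])
    def test_cutoff_boundary(self, pct, group):
        assert cm.assign_risk_group(pct) == group

    def test_percentile_out_of_range(self):
        with pytest.raises(ValueError):
            cm.assign_risk_group(101.0)


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        s = cm.km_estimate([1, 2, 3], [1, 1, 1])
        assert np.isclose(s.loc[1.0], 2.0 / 3.0)
        assert np.isclose(s.loc[2.0], 1.0 / 3.0)
        assert np.isclose(s.loc[3.0], 0.0)

    def test_censoring_reduces_risk_set(self):
        s = cm.km_estimate([1, 2, 3], [0, 1, 1])
        assert np.isclose(s.loc[2.0], 0.5)
        assert np.isclose(s.loc[3.0], 0.0)

    def test_all_censored_flat_at_one(self):
        s = cm.km_estimate([1, 2, 3], [0, 0, 0])
        assert (s == 1.0).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cm.km_estimate([-1, 2], [1, 1])

    def test_nonincreasing_from_one(self, rng):
        t = rng.exponential(size=50)
        e = rng.random(50) < 0.6
        s = cm.km_estimate(t, e)
        assert s.iloc[0] == 1.0
        assert (np.diff(s.to_numpy()) <= 1e-12).all()


class TestLogRank:
    def test_identical_groups_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = ["a"] * 4 + ["b"] * 4
        assert cm.logrank_statistic(g, t, e) == 0.0

    def test_matches_lifelines(self, rng):
        t = rng.exponential(size=60)
        e = rng.random(60) < 0.8
        g = np.where(rng.random(60) < 0.5, "a", "b")
        ours = cm.logrank_statistic(g, t, e)
        ref = logrank_test(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert np.isclose(ours, ref.test_statistic, atol=1e-8)

    def test_group_label_and_time_scale_symmetry(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 0, 1])
        g = np.array(["a", "b", "a", "b", "a", "b"])
        base = cm.logrank_statistic(g, t, e)
        swapped = cm.logrank_statistic(np.where(g == "a", "b", "a"), t, e)
        assert np.isclose(base, swapped, atol=1e-12)
        rescaled = cm.logrank_statistic(g, 7.0 * t, e)  # rank statistic
        assert np.isclose(base, rescaled, atol=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 nonempty groups"):
            cm.logrank_statistic(["a", "a"], [1, 2], [1, 1])


class TestLOOCV:
    def test_shape_labels_and_determinism(self, planted_survival_data):
        X, t, e = planted_survival_data
        a = cm.loocv_risk_groups(X, t, e)
        b = cm.loocv_risk_groups(X, t, e)
        assert len(a) == X.shape[1]
        assert set(a["group"]) <= {"low", "high"}
        pd.testing.assert_frame_equal(a, b)

    def test_separates_planted_risk(self, planted_survival_data):
        X, t, e = planted_survival_data
        cv = cm.loocv_risk_groups(X, t, e)
        hi = (cv["group"] == "high").to_numpy()
        assert 0 < hi.sum() < len(cv)
        lr = cm.logrank_statistic(cv["group"], t, e)
        assert lr > 3.84  # beyond the chi-square 95th percentile

    def test_needs_ten_samples(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError, match="n >= 10"):
            cm.loocv_risk_groups(X, np.arange(6.0) + 1, np.ones(6, bool))


class TestPermutation:
    def test_deterministic_under_seed(self, planted_survival_data):
        X, t, e = planted_survival_data
        a = cm.permutation_significance(X, t, e, n_perm=19, seed=5)
        b = cm.permutation_significance(X, t, e, n_perm=19, seed=5)
        assert a.p == b.p and a.lr_observed == b.lr_observed
        assert np.array_equal(a.null_stats, b.null_stats)

    def test_strong_signal_reaches_minimum_p(self, planted_survival_data):
        X, t, e = planted_survival_data
        res = cm.permutation_significance(X, t, e, n_perm=19, seed=5)
        assert res.p == 1.0 / 20.0  # observed exceeds every permutation
        assert (res.null_stats < res.lr_observed).all()

    def test_observed_statistic_invariant_to_sample_order(self,
                                                          planted_survival_data):
        X, t, e = planted_survival_data
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[1])
        a = cm.permutation_significance(X, t, e, n_perm=19, seed=1)
        b = cm.permutation_significance(X.iloc[:, perm], t[perm], e[perm],
                                        n_perm=19, seed=1)
        assert np.isclose(a.lr_observed, b.lr_observed, atol=1e-8)

    def test_n_perm_floor(self, planted_survival_data):
        X, t, e = planted_survival_data
        with pytest.raises(ValueError, match="19"):
            cm.permutation_significance(X, t, e, n_perm=5)
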