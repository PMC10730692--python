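import numpy as np
import pandas as pd
import pytest

from bctwohit import riskmodel as rm
from bctwohit.simulate import SimulationConfig, simulate_cohort

from conftest import auc_oracle


class TestPublishedCalculators:
    def test_origin_scores_are_the_intercepts(self):
        origin = pd.Series({c: 0.0 for c in rm.bcdg_model().covariates})
        assert rm.bcdg_model().linear_predictor(origin)[0] == pytest.approx(-1.561)
        assert rm.two_hit_model().linear_predictor(origin)[0] == pytest.approx(-2.371)

    def test_age_only_patient(self):
        row = pd.Series({c: 0.0 for c in rm.bcdg_model().covariates})
        row["age"] = 40
        assert rm.bcdg_model().linear_predictor(row)[0] == pytest.approx(-1.561 - 0.039 * 40)

    def test_linear_predictor_is_affine(self, rng):
        spec = rm.bcdg_model()
        a = pd.Series({c: rng.uniform(0, 3) for c in spec.covariates})
        b = pd.Series({c: rng.uniform(0, 3) for c in spec.covariates})
        diff = spec.linear_predictor(a)[0] - spec.linear_predictor(b)[0]
        manual = sum(spec.coefficients[c] * (a[c] - b[c]) for c in spec.covariates)
        assert diff == pytest.approx(manual)

    def test_unknown_covariate_raises(self):
        with pytest.raises(KeyError):
            rm.bcdg_model().linear_predictor(pd.Series({"age": 40}))

    def test_probability_is_logistic_of_score(self):
        spec = rm.two_hit_model()
        row = pd.Series({c: 1.0 for c in spec.covariates})
        score, prob = rm.linear_predictor(spec, row)
        assert prob[0] == pytest.approx(1 / (1 + np.exp(-score[0])))


class TestFitLogistic:
    def test_single_binary_covariate_matches_sample_log_or(self, rng):
        x = np.repeat([0, 1], 200)
        y = np.r_[rng.random(200) < 0.2, rng.random(200) < 0.5].astype(int)
        res = rm.LogisticRiskModel(y, pd.DataFrame({"x": x})).fit()
        a, b = y[x == 1].sum(), (1 - y[x == 1]).sum()
        c, d = y[x == 0].sum(), (1 - y[x == 0]).sum()
        assert res.params["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-4)

    def test_null_covariates_give_small_z(self, rng):
        n = 10_000
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=list("abc"))
        y = (rng.random(n) < 0.3).astype(int)
        res = rm.LogisticRiskModel(y, X).fit()
        z = (res.params / res.bse).drop("const")
        assert (z.abs() < 3).all()

    def test_constant_outcome_raises(self):
        with pytest.raises(ValueError, match="constant"):
            rm.LogisticRiskModel(np.ones(20), pd.DataFrame({"x": np.arange(20)}))

    def test_separable_data_falls_back_to_penalty(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.astype(int)  # perfectly separable
        res = rm.LogisticRiskModel(y, pd.DataFrame({"x": x})).fit()
        assert np.isfinite(res.params).all()

    def test_recovers_printed_coefficients_in_ci(self):
        """Refit on a cohort simulated from the published calculator."""
        spec = rm.bcdg_model()
        sim = simulate_cohort(SimulationConfig(seed=77, n_patients=4000,
                                               covariate_missing_rate=0.0))
        df = sim.truth["clinical_complete"].copy()
        df["carrier"] = sim.truth["carrier"]["bcdg_carrier"].astype(int).to_numpy()
        res = rm.LogisticRiskModel.from_dataframe(df, "carrier", spec.covariates).fit()
        ci = res.conf_int()
        truth = {"const": spec.intercept, **spec.coefficients}
        inside = sum(ci.loc[k, "lo"] <= v <= ci.loc[k, "hi"] for k, v in truth.items())
        assert inside >= 12  # ~95% coverage over 14 parameters

    def test_summary_lists_every_covariate(self):
        spec = rm.bcdg_model()
        sim = simulate_cohort(SimulationConfig(seed=78, n_patients=2000,
                                               covariate_missing_rate=0.0))
        df = sim.truth["clinical_complete"].copy()
        df["carrier"] = sim.truth["carrier"]["bcdg_carrier"].astype(int).to_numpy()
        text = rm.LogisticRiskModel.from_dataframe(df, "carrier", spec.covariates).fit().summary()
        assert all(c in text for c in spec.covariates)


class TestSplit:
    @pytest.fixture
    def frame(self):
        return pd.DataFrame({"x": np.arange(1000)})

    def test_sizes(self, frame):
        train, valid = rm.split_train_validation(frame, 0.7, seed=0)
        assert len(train) == 700 and len(valid) == 300

    def test_deterministic_and_partitioning(self, frame):
        t1, v1 = rm.split_train_validation(frame, 0.7, seed=9)
        t2, v2 = rm.split_train_validation(frame, 0.7, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        union = set(t1["x"]) | set(v1["x"])
        assert union == set(frame["x"]) and not set(t1["x"]) & set(v1["x"])

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError):
            rm.split_train_validation(pd.DataFrame({"x": range(5)}), 0.7, 0)


class TestImputation:
    def test_complete_data_returned_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = rm.impute_chained(df)
        pd.testing.assert_frame_equal(out.data, df)

    def test_imputed_value_within_observed_range(self, rng):
        a = rng.normal(50, 5, 200)
        b = 2 * a + rng.normal(0, 1, 200)
        df = pd.DataFrame({"a": a, "b": b})
        df.loc[5, "b"] = np.nan
        out = rm.impute_chained(df, seed=1)
        assert df["b"].min() <= out.data.loc[5, "b"] <= df["b"].max()
        assert out.mask.loc[5, "b"]

    def test_regression_imputation_tracks_predictor(self, rng):
        a = rng.normal(0, 1, 500)
        b = 3 * a + rng.normal(0, 0.1, 500)
        df = pd.DataFrame({"a": a, "b": b})
        holes = rng.choice(500, 50, replace=False)
        df.loc[holes, "b"] = np.nan
        out = rm.impute_chained(df, seed=2)
        err = out.data.loc[holes, "b"] - 3 * df.loc[holes, "a"]
        assert np.abs(err).mean() < 0.5

    def test_deterministic_under_seed(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100)})
        df.loc[:10, "b"] = np.nan
        out1 = rm.impute_chained(df, seed=3)
        out2 = rm.impute_chained(df, seed=3)
        pd.testing.assert_frame_equal(out1.data, out2.data)

    def test_fully_missing_column_raises(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="fully missing"):
            rm.impute_chained(df)

    def test_rubin_pooling_combines_m_datasets(self, rng):
        a = rng.normal(0, 1, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-a))).astype(int)
        df = pd.DataFrame({"a": a, "b": a + rng.normal(0, 1, 400)})
        df.loc[rng.choice(400, 40, replace=False), "b"] = np.nan
        imp = rm.impute_chained(df, seed=4, m=3)
        fits = [rm.LogisticRiskModel(y, d[["a", "b"]]).fit() for d in imp.datasets]
        pooled = rm.pool_rubin(fits)
        assert set(pooled.index) == {"const", "a", "b"}
        assert (pooled["se"] >= fits[0].bse * 0.5).all()


class TestMetrics:
    def test_perfect_separation_auc_one(self):
        auc, _ = rm.roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0

    def test_one_swap_matches_pair_enumeration(self):
        scores, labels = [1, 2, 3, 4], [0, 1, 0, 1]
        auc, _ = rm.roc_auc(scores, labels)
        assert auc == pytest.approx(auc_oracle(scores, labels))

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(0, 1, 10_000)
        labels = rng.random(10_000) < 0.5
        auc, (lo, hi) = rm.roc_auc(scores, labels.astype(int))
        assert lo <= 0.5 <= hi
        assert abs(auc - 0.5) < 0.02

    def test_auc_with_ties_matches_oracle(self, rng):
        scores = rng.integers(0, 4, 60).astype(float)
        labels = (rng.random(60) < 0.4).astype(int)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        auc, _ = rm.roc_auc(scores, labels)
        assert auc == pytest.approx(auc_oracle(scores, labels))

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(0, 1, 500)
        labels = (rng.random(500) < 0.3).astype(int)
        a1, _ = rm.roc_auc(scores, labels)
        a2, _ = rm.roc_auc(np.exp(2 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            rm.roc_auc([1, 2, 3], [1, 1, 1])

    def test_hl_rejects_miscalibration(self, rng):
        probs = rng.uniform(0.1, 0.6, 5000)
        y = rng.random(5000) < np.clip(probs - 0.2, 0, 1)
        _, p = rm.hosmer_lemeshow(probs + 0.2, y.astype(float))
        assert p < 0.05

    def test_hl_identical_probs_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            rm.hosmer_lemeshow(np.full(100, 0.3), np.zeros(100))

    def test_threshold_symmetric_distributions(self, rng):
        scores = np.r_[rng.normal(-1, 1, 4000), rng.normal(1, 1, 4000)]
        labels = np.r_[np.zeros(4000), np.ones(4000)]
        thr, sens, spec = rm.choose_threshold(scores, labels)
        assert abs(thr) < 0.15
        assert abs(sens - spec) < 0.02

    def test_threshold_gap_midpoint_on_separated_scores(self):
        thr, sens, spec = rm.choose_threshold([0, 1, 10, 11], [0, 0, 1, 1])
        assert thr == pytest.approx(5.5)
        assert sens == 1.0 and spec == 1.0

    def test_threshold_matches_exhaustive_scan(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        thr, sens, spec = rm.choose_threshold(scores, labels)
        uniq = np.unique(scores)
        best = None
        for t in (uniq[:-1] + uniq[1:]) / 2:
            pos = np.asarray(scores) >= t
            s = (pos & (np.asarray(labels) == 1)).sum() / 2
            c = (~pos & (np.asarray(labels) == 0)).sum() / 2
            key = (abs(s - c), -s)
            if best is None or key < best[0]:
                best = (key, t, s, c)
        assert (thr, sens, spec) == pytest.approx((best[1], best[2], best[3]))


class TestEndToEndValidation:
    def test_validate_reports_coherent_metrics(self):
        spec = rm.bcdg_model()
        sim = simulate_cohort(SimulationConfig(seed=31, n_patients=3000))
        df = sim.clinical.copy()
        df["carrier"] = sim.truth["carrier"]["bcdg_carrier"].astype(int).to_numpy()
        completed = rm.impute_chained(df, seed=31, columns=spec.covariates).data
        train, valid = rm.split_train_validation(completed, 0.7, seed=31)
        res = rm.LogisticRiskModel.from_dataframe(train, "carrier", spec.covariates).fit()
        report = res.validate(valid[spec.covariates], valid["carrier"])
        assert 0.5 < report.auc <= 1.0
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
        assert 0 <= report.sensitivity <= 1 and 0 <= report.specificity <= 1
        assert 0 <= report.hl_p <= 1
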