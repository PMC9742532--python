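"""Score tables, the classifier stage, streamlining and explanations."""

import numpy as np
import pandas as pd
import pytest

from dmscreen.riskmodels import (
    LEARNER_KINDS,
    ExplanationVector,
    RiskModelError,
    ScoreTable,
    apply_score_table,
    contributions_to_rr,
    cross_validate,
    explain,
    fit,
    impute,
    load_score_table,
    rank_features,
    streamline,
)
from tests.conftest import MODEL_FEATURES, two_blobs

TOY_TABLE = ScoreTable.from_dict({
    "name": "toy",
    "cutoff": 4,
    "items": [
        {"feature": "age", "bins": [
            {"lo": None, "hi": 40, "points": 0},
            {"lo": 40, "hi": 60, "points": 2},
            {"lo": 60, "hi": None, "points": 4}]},
        {"feature": "bmi", "bins": [
            {"lo": None, "hi": 24, "points": 0},
            {"lo": 24, "hi": None, "points": 2}]},
    ],
})


class TestScoreTable:
    def test_forced_sum(self):
        person = pd.DataFrame({"age": [55.0], "bmi": [25.0]})
        scores, flags = apply_score_table(TOY_TABLE, person)
        assert scores[0] == 4 and flags[0]

    def test_cutoff_zero_everyone_positive(self, small_cohort):
        table = ScoreTable(name="z", items=TOY_TABLE.items, cutoff=0)
        _, flags = apply_score_table(table, small_cohort)
        assert flags.all()

    def test_matches_per_row_lookup_oracle(self, small_cohort):
        pop = small_cohort.head(1000)
        scores, flags = apply_score_table(TOY_TABLE, pop)

        def lookup(row):
            total = 0
            for feature, bins in TOY_TABLE.items:
                v = row[feature]
                for b in bins:
                    lo = -np.inf if b.lo is None else b.lo
                    hi = np.inf if b.hi is None else b.hi
                    if lo <= v < hi:
                        total += b.points
                        break
            return total

        expect = pop.apply(lookup, axis=1).to_numpy()
        np.testing.assert_array_equal(scores, expect)
        np.testing.assert_array_equal(flags, expect >= TOY_TABLE.cutoff)

    def test_categorical_value_outside_bins_is_reported(self):
        table = load_score_table("ncdrs_placeholder")
        pop = pd.DataFrame({"age": [50.0], "sex": ["unknown"], "bmi": [24.0],
                            "wc": [80.0], "sbp": [130.0]})
        with pytest.raises(RiskModelError, match="sex"):
            apply_score_table(table, pop)

    def test_gappy_numeric_bins_rejected(self):
        with pytest.raises(RiskModelError, match="contiguous"):
            ScoreTable.from_dict({
                "name": "bad", "cutoff": 1,
                "items": [{"feature": "age", "bins": [
                    {"lo": None, "hi": 40, "points": 0},
                    {"lo": 50, "hi": None, "points": 1}]}]})

    def test_shipped_placeholders_load_and_roundtrip(self):
        for name in ("ncdrs_placeholder", "adart_placeholder"):
            t = load_score_table(name)
            again = ScoreTable.from_dict(t.to_dict())
            assert again.to_dict() == t.to_dict()


class TestImpute:
    def test_complete_tables_unchanged(self, dev_test_split):
        dev, test = dev_test_split
        dev2, test2 = impute(dev, test)
        pd.testing.assert_frame_equal(dev2, dev)
        pd.testing.assert_frame_equal(test2, test)

    def test_beats_median_imputation_on_known_truth(self, small_cohort):
        rng = np.random.default_rng(0)
        pop = small_cohort.reset_index(drop=True)
        truth = pop["sbp"].to_numpy().copy()
        masked = pop.copy()
        holes = rng.random(len(pop)) < 0.10
        masked.loc[holes, "sbp"] = np.nan
        dev2, _ = impute(masked, masked.head(50))
        rmse = np.sqrt(np.mean((dev2.loc[holes, "sbp"] - truth[holes]) ** 2))
        rmse_median = np.sqrt(np.mean((np.nanmedian(masked["sbp"]) - truth[holes]) ** 2))
        assert rmse <= rmse_median

    def test_test_set_never_influences_dev_model(self, dev_test_split):
        dev, test = dev_test_split
        rng = np.random.default_rng(1)
        test_a = test.copy()
        test_b = test.copy()
        holes = rng.random(len(test)) < 0.1
        test_a.loc[holes, "wc"] = np.nan
        test_b.loc[holes, "wc"] = np.nan
        test_b.loc[~holes, "wc"] = test_b.loc[~holes, "wc"] + 50  # corrupt observed test values
        _, filled_a = impute(dev, test_a)
        _, filled_b = impute(dev, test_b)
        # univariate fill from the dev model must not move with test data
        # (multivariate fills depend on the row's own other columns, which are equal)
        pd.testing.assert_series_equal(filled_a.loc[holes, "wc"],
                                       filled_b.loc[holes, "wc"])

    def test_heavily_missing_column_dropped_with_warning(self, dev_test_split, caplog):
        dev, test = dev_test_split
        dev = dev.copy()
        dev["mostly_gone"] = np.nan
        test = test.copy()
        test["mostly_gone"] = 1.0
        with caplog.at_level("WARNING", logger="dmscreen"):
            dev2, test2 = impute(dev, test)
        assert "mostly_gone" not in dev2.columns
        assert "mostly_gone" not in test2.columns
        assert "mostly_gone" in caplog.text


class TestFit:
    @pytest.mark.parametrize("learner", LEARNER_KINDS)
    def test_separable_blobs_high_auc(self, learner):
        from sklearn.metrics import roc_auc_score
        train = two_blobs(400, seed=1)
        held = two_blobs(300, seed=2)
        model = fit(train, learner, ["f1", "f2"], seed=0)
        preds = model.predict_risk(held)
        assert np.all((preds >= 0) & (preds <= 1))
        assert roc_auc_score(held["dm_status"], preds) > 0.95

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(3)
        dev = two_blobs(5000, separation=2.0, seed=4)
        dev["dm_status"] = rng.permutation(dev["dm_status"].to_numpy())
        cv = cross_validate(dev, "LOGISTIC", ["f1", "f2"], k=5, seed=0, n_boot=0)
        assert 0.45 <= cv["pooled_auc"] <= 0.55

    def test_seed_determinism(self, dev_test_split):
        dev, test = dev_test_split
        for learner in ("GRADIENT_BOOSTED_TREES", "NEURAL_NET", "RANDOM_FOREST"):
            a = fit(dev, learner, MODEL_FEATURES, seed=5).predict_risk(test)
            b = fit(dev, learner, MODEL_FEATURES, seed=5).predict_risk(test)
            np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        dev = two_blobs(100, seed=5)
        dev["dm_status"] = True
        with pytest.raises(RiskModelError, match="both classes"):
            fit(dev, "LOGISTIC", ["f1", "f2"], seed=0)

    def test_base_rate_is_training_prevalence(self):
        dev = two_blobs(200, seed=6, prevalence=0.25)
        model = fit(dev, "LOGISTIC", ["f1", "f2"], seed=0)
        assert model.base_rate == pytest.approx(0.25)


class TestCrossValidate:
    def test_fold_sizes_near_equal(self):
        dev = two_blobs(5055, separation=1.0, seed=7)
        cv = cross_validate(dev, "LOGISTIC", ["f1", "f2"], k=5, seed=1, n_boot=0)
        assert cv["per_fold"]["n"].tolist() == [1011] * 5

    def test_clairvoyant_learner_auc_one(self):
        dev = two_blobs(300, separation=50.0, seed=8)  # effectively the label
        cv = cross_validate(dev, "LOGISTIC", ["f1", "f2"], k=5, seed=2, n_boot=0)
        assert cv["pooled_auc"] == pytest.approx(1.0)

    def test_constant_learner_pr_baseline_is_prevalence(self):
        # an uninformative feature yields a constant prediction within each
        # fold: fold AUC is exactly one half and fold auPR the fold prevalence
        dev = two_blobs(600, seed=9, prevalence=0.2)
        dev["flat"] = 1.0
        cv = cross_validate(dev, "LOGISTIC", ["flat"], k=5, seed=3, n_boot=0)
        folds = np.array_split(np.random.default_rng(3).permutation(len(dev)), 5)
        y = dev["dm_status"].to_numpy()
        for row, idx in zip(cv["per_fold"].itertuples(), folds):
            assert row.auc == pytest.approx(0.5, abs=1e-12)
            assert row.aupr == pytest.approx(y[idx].mean(), abs=1e-12)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(RiskModelError):
            cross_validate(two_blobs(4), "LOGISTIC", ["f1"], k=10)


class TestExplanations:
    @pytest.mark.parametrize("learner", ["GRADIENT_BOOSTED_TREES", "LOGISTIC"])
    def test_additivity_reproduces_log_odds(self, dev_test_split, learner):
        dev, test = dev_test_split
        model = fit(dev, learner, MODEL_FEATURES, seed=0)
        rows = test.head(40)
        risks = model.predict_risk(rows)
        log_odds = np.log(risks / (1 - risks))
        for e, lo in zip(explain(model, rows), log_odds):
            assert e.fx == pytest.approx(lo, abs=1e-6)

    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(10)
        n = 2000
        y = rng.random(n) < 0.3
        dev = pd.DataFrame({
            "signal": y + rng.normal(0, 0.3, n),
            "noise_a": rng.normal(size=n),
            "noise_b": rng.normal(size=n),
            "dm_status": y,
        })
        for learner in ("GRADIENT_BOOSTED_TREES", "LOGISTIC", "KNN"):
            model = fit(dev, learner, ["signal", "noise_a", "noise_b"], seed=0)
            assert rank_features(model, dev)[0][0] == "signal", learner

    def test_constant_features_zero_importance_lexicographic(self):
        rng = np.random.default_rng(11)
        n = 300
        dev = pd.DataFrame({
            "b_const": np.ones(n), "a_const": np.zeros(n),
            "dm_status": rng.random(n) < 0.5,
        })
        model = fit(dev, "GRADIENT_BOOSTED_TREES", ["b_const", "a_const"], seed=0)
        ranking = rank_features(model, dev)
        assert [r[0] for r in ranking] == ["a_const", "b_const"]
        assert all(r[1] == 0 for r in ranking)

    def test_rank_invariant_to_row_order(self, dev_test_split):
        dev, _ = dev_test_split
        model = fit(dev, "GRADIENT_BOOSTED_TREES", MODEL_FEATURES, seed=0)
        a = rank_features(model, dev)
        b = rank_features(model, dev.sample(frac=1.0, random_state=3))
        assert [f for f, _ in a] == [f for f, _ in b]

    def test_relative_risk_closed_forms(self):
        e = ExplanationVector(features=["x"], phi=np.array([0.0]), base=0.3)
        assert contributions_to_rr(e, "x") == pytest.approx(1.0)
        e2 = ExplanationVector(features=["x"], phi=np.array([np.log(3.0)]), base=0.0)
        assert contributions_to_rr(e2, "x") == pytest.approx(1.5)
        e3 = ExplanationVector(features=["x"], phi=np.array([-0.4]), base=0.1)
        assert contributions_to_rr(e3, "x") < 1.0
        with pytest.raises(RiskModelError):
            contributions_to_rr(
                ExplanationVector(["x"], np.array([np.inf]), 0.0), "x")

    def test_rpr_relative_risk_crosses_one_near_cohort_center(self, dev_test_split):
        """Resting pulse rate contributes positive risk above the cohort's
        typical value and negative below it, by the generator's construction."""
        dev, test = dev_test_split
        model = fit(dev, "GRADIENT_BOOSTED_TREES", MODEL_FEATURES, seed=0)
        rows = test.head(500)
        rrs = np.array([contributions_to_rr(e, "rpr")
                        for e in explain(model, rows)])
        rpr = rows["rpr"].to_numpy()
        assert rrs[rpr > 95].mean() > 1.0
        assert rrs[rpr < 70].mean() < 1.0


class TestStreamline:
    def test_five_informative_features_choose_k5(self):
        rng = np.random.default_rng(12)
        n = 3000
        y = rng.random(n) < 0.3
        cols = {f"sig_{i}": y * 1.0 + rng.normal(0, 0.7, n) for i in range(5)}
        cols |= {f"noise_{i}": rng.normal(size=n) for i in range(10)}
        dev = pd.DataFrame(cols)
        dev["dm_status"] = y
        k, model, table = streamline(dev, "GRADIENT_BOOSTED_TREES",
                                     ks=(5, 10, 15), tolerance=0.01, seed=0)
        assert k == 5
        assert all(f.startswith("sig_") for f in model.feature_list)

    def test_tolerance_zero_takes_argmax(self, dev_test_split):
        dev, _ = dev_test_split
        k, model, table = streamline(dev, "GRADIENT_BOOSTED_TREES",
                                     ks=(3, 6), tolerance=0.0, seed=0)
        best = table.loc[table["auc"].idxmax(), "k"]
        assert k == best
        assert table.loc[table["k"] == k, "auc"].iloc[0] >= table["auc"].max() - 1e-12

    def test_empty_or_unsorted_ks_rejected(self, dev_test_split):
        dev, _ = dev_test_split
        with pytest.raises(RiskModelError):
            streamline(dev, ks=())
        with pytest.raises(RiskModelError):
            streamline(dev, ks=(10, 5))
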