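import numpy as np
import pandas as pd
import pytest

import tremornet as tn
from tremornet import classify
from tremornet.errors import ConfigurationError, UsageError, ValidationError


def gaussian_table(n_td=69, n_et=71, d_prime=1.5, n_noise=9, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["TD"] * n_td + ["ET"] * n_et)
    X = pd.DataFrame({
        "signal": np.where(y == "TD", d_prime, 0.0) + rng.standard_normal(y.size),
        **{f"noise{i}": rng.standard_normal(y.size) for i in range(n_noise)},
    })
    return classify.FeatureTable(X=X, labels=y)


class TestSplit:
    def test_140_subjects_split_105_35(self):
        table = gaussian_table()
        train, test = classify.split_train_test(table, seed=0)
        assert train.X.shape[0] == 105
        assert test.X.shape[0] == 35
        # stratification within one subject
        for cls in ("TD", "ET"):
            frac_all = (table.labels == cls).mean()
            frac_tr = (train.labels == cls).mean()
            assert abs(frac_tr - frac_all) * train.X.shape[0] <= 1.5

    def test_deterministic_per_seed(self):
        table = gaussian_table()
        a1, _ = classify.split_train_test(table, seed=5)
        a2, _ = classify.split_train_test(table, seed=5)
        assert list(a1.X.index) == list(a2.X.index)

    def test_disjoint_exhaustive(self):
        table = gaussian_table()
        train, test = classify.split_train_test(table, seed=1)
        ids = set(train.X.index) | set(test.X.index)
        assert len(ids) == 140
        assert not (set(train.X.index) & set(test.X.index))

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        table = classify.FeatureTable(
            X=pd.DataFrame({"a": rng.standard_normal(10)}),
            labels=np.array(["TD"] * 10),
        )
        with pytest.raises(UsageError):
            classify.split_train_test(table, seed=0)

    def test_too_few_subjects_rejected(self):
        table = classify.FeatureTable(
            X=pd.DataFrame({"a": [1.0, 2, 3, 4]}),
            labels=np.array(["TD", "TD", "ET", "ET"]),
        )
        with pytest.raises(UsageError):
            classify.split_train_test(table, seed=0)


class TestStabilitySelection:
    def test_signal_separates_from_noise(self):
        # one feature that is the labels plus tiny noise, nine pure noise
        rng = np.random.default_rng(0)
        y = np.array(["TD"] * 69 + ["ET"] * 71)
        X = pd.DataFrame({
            "signal": (y == "TD").astype(float) + 0.05 * rng.standard_normal(y.size),
            **{f"noise{i}": rng.standard_normal(y.size) for i in range(9)},
        })
        table = classify.FeatureTable(X=X, labels=y)
        train, _ = classify.split_train_test(table, seed=0)
        profile = classify.lasso_stability_select(
            train, n_repeats=100, threshold=50, seed=1
        )
        assert profile.counts["signal"] >= 90
        assert profile.selected[0] == "signal"
        noise_counts = profile.counts.drop("signal")
        assert (noise_counts <= 50).all()

    def test_count_threshold_is_strict(self):
        table = gaussian_table(d_prime=3.0, n_noise=3)
        train, _ = classify.split_train_test(table, seed=0)
        profile = classify.lasso_stability_select(
            train, n_repeats=50, threshold=50, seed=1
        )
        # a feature selected in every repeat has count == n_repeats == threshold,
        # which is NOT strictly greater
        assert profile.selected == []

    def test_top_30pct_mode(self):
        table = gaussian_table(n_noise=9)
        train, _ = classify.split_train_test(table, seed=0)
        profile = classify.lasso_stability_select(
            train, n_repeats=30, mode="top_30pct", seed=1
        )
        assert len(profile.selected) == 3  # ceil(0.3 * 10)

    def test_constant_feature_dropped_with_warning(self):
        table = gaussian_table(n_noise=2)
        X = table.X.copy()
        X["flat"] = 1.0
        t2 = classify.FeatureTable(X=X, labels=table.labels)
        train, _ = classify.split_train_test(t2, seed=0)
        with pytest.warns(UserWarning, match="flat"):
            profile = classify.lasso_stability_select(
                train, n_repeats=20, threshold=10, seed=1
            )
        assert "flat" not in profile.counts.index

    def test_selection_ignores_test_split(self):
        """Pipeline hygiene: corrupting test labels cannot change the profile."""
        table = gaussian_table()
        train, test = classify.split_train_test(table, seed=0)
        p1 = classify.lasso_stability_select(train, n_repeats=30, threshold=15, seed=2)
        test.labels[:] = "TD"  # corrupt the held-out labels
        p2 = classify.lasso_stability_select(train, n_repeats=30, threshold=15, seed=2)
        pd.testing.assert_series_equal(p1.counts, p2.counts)


class TestTrainModels:
    def test_separable_data_perfect_cv_auc(self):
        y = np.array(["TD"] * 20 + ["ET"] * 20)
        X = pd.DataFrame({"f": np.where(y == "TD", 1.0, -1.0)})
        table = classify.FeatureTable(X=X, labels=y)
        bundle = classify.train_models(table, ["f"], learners=("SVM-linear", "RF"), seed=0)
        assert bundle["cv_auc"]["SVM-linear"] == pytest.approx(1.0)
        assert bundle["cv_auc"]["RF"] == pytest.approx(1.0)

    def test_empty_selection_rejected(self):
        table = gaussian_table()
        with pytest.raises(ConfigurationError, match="top_30pct"):
            classify.train_models(table, [], seed=0)

    def test_fixed_seed_reproduces_hyperparameters(self):
        table = gaussian_table(n_noise=2)
        train, _ = classify.split_train_test(table, seed=0)
        b1 = classify.train_models(train, ["signal"], learners=("SVM-rbf",), seed=3)
        b2 = classify.train_models(train, ["signal"], learners=("SVM-rbf",), seed=3)
        assert b1["params"] == b2["params"]

    def test_unknown_learner_rejected(self):
        table = gaussian_table(n_noise=1)
        with pytest.raises(UsageError):
            classify.train_models(table, ["signal"], learners=("XGB",), seed=0)


class _RankModel:
    """Duck-typed probability model for AUC invariance checks."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        s = self.scores[: X.shape[0]]
        return np.column_stack([1 - s, s])


class TestEvaluateResampledAUC:
    def test_perfect_predictions_give_auc_one(self):
        y = np.array(["TD"] * 10 + ["ET"] * 10)
        X = pd.DataFrame({"f": np.zeros(20)})
        test = classify.FeatureTable(X=X, labels=y)
        bundle = {"features": ["f"], "models": {"M": _RankModel(test.y.astype(float))}}
        evals = classify.evaluate_resampled_auc(bundle, test, n_resamples=50, seed=0)
        assert np.all(evals["M"].auc_samples == 1.0)

    def test_monotone_transform_leaves_auc_unchanged(self):
        rng = np.random.default_rng(0)
        y = np.array(["TD", "ET"] * 15)
        scores = rng.random(30)
        X = pd.DataFrame({"f": np.zeros(30)})
        test = classify.FeatureTable(X=X, labels=y)
        bundle = {
            "features": ["f"],
            "models": {"raw": _RankModel(scores),
                       "warped": _RankModel(1 / (1 + np.exp(-8 * (scores - 0.5))))},
        }
        evals = classify.evaluate_resampled_auc(bundle, test, n_resamples=100, seed=1)
        np.testing.assert_array_equal(
            evals["raw"].auc_samples, evals["warped"].auc_samples
        )

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(2)
        y = np.array(["TD", "ET"] * 40)
        X = pd.DataFrame({"f": np.zeros(80)})
        test = classify.FeatureTable(X=X, labels=y)
        bundle = {"features": ["f"], "models": {"M": _RankModel(rng.random(80))}}
        evals = classify.evaluate_resampled_auc(bundle, test, n_resamples=300, seed=3)
        assert 0.4 < evals["M"].mean_auc < 0.6

    def test_single_class_test_rejected(self):
        X = pd.DataFrame({"f": np.zeros(5)})
        test = classify.FeatureTable(X=X, labels=np.array(["TD"] * 5))
        with pytest.raises(UsageError):
            classify.evaluate_resampled_auc(
                {"features": ["f"], "models": {}}, test, seed=0
            )

    def test_ci_within_sample_range(self):
        rng = np.random.default_rng(4)
        y = np.array(["TD", "ET"] * 20)
        X = pd.DataFrame({"f": np.zeros(40)})
        test = classify.FeatureTable(X=X, labels=y)
        bundle = {"features": ["f"], "models": {"M": _RankModel(rng.random(40))}}
        e = classify.evaluate_resampled_auc(bundle, test, n_resamples=200, seed=5)["M"]
        assert e.auc_samples.min() <= e.ci_low <= e.ci_high <= e.auc_samples.max()


class TestBuildFeatureTable:
    def test_patients_only_and_tags(self, small_cohort):
        for fs in classify.FEATURE_SETS:
            table = classify.build_feature_table(small_cohort, fs)
            assert set(np.unique(table.labels)) == {"TD", "ET"}
            assert table.feature_set == fs
        morph = classify.build_feature_table(small_cohort, "morphology")
        assert "Pallidum.L" in morph.X.columns
        clin = classify.build_feature_table(small_cohort, "clinical")
        assert "MoCA" in clin.X.columns and "Pallidum.L" not in clin.X.columns

    def test_unknown_feature_set(self, small_cohort):
        with pytest.raises(UsageError):
            classify.build_feature_table(small_cohort, "imaging")


def test_full_pipeline_reproducible():
    table = gaussian_table(d_prime=2.0, n_noise=3)

    def run():
        train, test = classify.split_train_test(table, seed=10)
        profile = classify.lasso_stability_select(train, n_repeats=20, threshold=10, seed=11)
        bundle = classify.train_models(
            train, profile.selected or ["signal"], learners=("SVM-linear",), seed=12
        )
        evals = classify.evaluate_resampled_auc(bundle, test, n_resamples=50, seed=13)
        return evals["SVM-linear"].auc_samples

    np.testing.assert_array_equal(run(), run())


def test_labels_validated():
    with pytest.raises(ValidationError):
        classify.FeatureTable(
            X=pd.DataFrame({"a": [1.0, 2.0]}), labels=np.array(["TD", "HC"])
        )
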