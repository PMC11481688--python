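import numpy as np
import pandas as pd
import pytest

from evpipe.aggregate_classifier import (
    MODEL_NAMES,
    TRAINING_COLUMNS,
    TrainingSet,
    build_training_set,
    decision_scores,
    evaluate,
    feature_importance,
    ml_correct,
    split_double_positive,
    train_model,
)
from evpipe.cluster_features import FEATURE_NAMES
from evpipe.phenotyping import summarize_counts


def feature_frame(n, rg_mean, seed, ch_counts=50):
    """Plausible feature rows around a given radius of gyration."""
    rng = np.random.default_rng(seed)
    rg = rng.lognormal(np.log(rg_mean), 0.3, n)
    hull = np.pi * rg**2 * rng.uniform(0.8, 1.2, n)
    nloc = rng.poisson(2 * ch_counts, n) + 1
    return pd.DataFrame(
        {
            "radius_of_gyration": rg,
            "num_localisations": nloc,
            "convex_hull_area": hull,
            "distance_birth": rg * 0.3,
            "skew": rng.uniform(0, 1, n),
            "discretised_area": hull * 0.5,
            "distance_depth": rg * 0.5,
            "circularity": rng.uniform(0.5, 1.0, n),
            "density": nloc / hull,
            "length": rg * 2.5,
            "ch1_binned_counts": rng.poisson(ch_counts, n),
            "ch2_binned_counts": rng.poisson(ch_counts, n),
        }
    )


@pytest.fixture
def separable_ts():
    dp = feature_frame(80, rg_mean=60.0, seed=0)
    ab = feature_frame(200, rg_mean=15.0, seed=1)
    return build_training_set(dp, ab)


class TestBuildTrainingSet:
    def test_row_counts(self):
        ts = build_training_set(feature_frame(10, 60, 0), feature_frame(100, 20, 1))
        assert int((ts.y == 1).sum()) == 20
        assert int((ts.y == 0).sum()) == 100
        assert len(ts.X) == 2 * 10 + 100

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            build_training_set(feature_frame(0, 60, 0), feature_frame(5, 20, 1))
        with pytest.raises(ValueError):
            build_training_set(feature_frame(5, 60, 0), feature_frame(0, 20, 1))

    def test_split_zeroes_cross_channel_counts(self):
        dp = feature_frame(4, 60, 0)
        views = split_double_positive(dp)
        assert len(views) == 8
        zeroed = (views["ch1_binned_counts"] == 0) | (views["ch2_binned_counts"] == 0)
        assert zeroed.all()

    def test_canonical_columns(self, separable_ts):
        assert list(separable_ts.X.columns) == TRAINING_COLUMNS

    def test_nan_features_imputed_with_indicator(self):
        dp = feature_frame(5, 60, 0)
        ab = feature_frame(5, 20, 1)
        ab.loc[0, "convex_hull_area"] = np.nan
        ts = build_training_set(dp, ab)
        assert not ts.X[FEATURE_NAMES].isna().any().any()
        assert ts.X["degenerate"].sum() == 1

    def test_precomputed_views_must_be_paired(self):
        dp = feature_frame(5, 60, 0)
        with pytest.raises(ValueError):
            build_training_set(dp, feature_frame(5, 20, 1), dp_views=feature_frame(3, 60, 2))


class TestTrainModel:
    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_separable_data_training_accuracy_one(self, separable_ts, model):
        clf = train_model(separable_ts, model, seed=0)
        assert (clf.predict(separable_ts.X) == separable_ts.y).mean() == 1.0

    def test_deterministic_given_seed(self, separable_ts):
        a = train_model(separable_ts, "random_forest", seed=42)
        b = train_model(separable_ts, "random_forest", seed=42)
        assert np.array_equal(a.predict(separable_ts.X), b.predict(separable_ts.X))
        assert np.allclose(
            decision_scores(a, separable_ts.X), decision_scores(b, separable_ts.X)
        )

    def test_single_class_is_error(self):
        ab = feature_frame(10, 20, 1)
        from evpipe.aggregate_classifier import _prepare

        ts = TrainingSet(X=_prepare(ab), y=np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            train_model(ts, "random_forest")

    def test_unknown_model_rejected(self, separable_ts):
        with pytest.raises(ValueError):
            train_model(separable_ts, "xgboost")

    def test_balanced_weights_help_minority_recall(self):
        # overlapping classes, 90:10 imbalance; balanced weighting should not
        # lose minority (positive) recall versus an unweighted counterpart
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        n_maj, n_min = 900, 100
        X = np.vstack(
            [rng.normal(0, 1, (n_maj, 3)), rng.normal(1.0, 1, (n_min, 3))]
        )
        y = np.r_[np.zeros(n_maj), np.ones(n_min)]
        wins = 0
        for seed in range(20):
            idx = np.random.default_rng(seed).permutation(len(y))
            bal = LogisticRegression(class_weight="balanced").fit(X[idx], y[idx])
            unw = LogisticRegression().fit(X[idx], y[idx])
            rec_bal = (bal.predict(X[y == 1]) == 1).mean()
            rec_unw = (unw.predict(X[y == 1]) == 1).mean()
            wins += rec_bal > rec_unw
        assert wins >= 15  # sign test: balanced wins in the vast majority of runs


def mann_whitney_auc(y, scores):
    """Independent oracle: AUC as the normalized Mann-Whitney U statistic."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        wins += (p > neg).sum() + 0.5 * (p == neg).sum()
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def test_perfect_separation_auc_one(self, separable_ts):
        clf = train_model(separable_ts, "random_forest", seed=0)
        m = evaluate(clf, separable_ts)
        assert m.auc_roc == pytest.approx(1.0)
        assert m.accuracy == 1.0
        assert m.precision == 1.0 and m.recall == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        scores = rng.uniform(size=10_000)
        assert mann_whitney_auc(y, scores) == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_mann_whitney_identity(self, separable_ts):
        # identity checked on <= 500 rows against the brute-force U statistic
        clf = train_model(separable_ts, "logistic_regression", seed=0)
        sub = TrainingSet(X=separable_ts.X.iloc[:250], y=separable_ts.y[:250])
        m = evaluate(clf, sub)
        oracle = mann_whitney_auc(sub.y, decision_scores(clf, sub.X))
        assert m.auc_roc == pytest.approx(oracle, abs=1e-12)

    def test_roc_endpoints(self, separable_ts):
        clf = train_model(separable_ts, "svm", seed=0)
        m = evaluate(clf, separable_ts)
        assert (m.roc_points.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (m.roc_points.iloc[-1][["fpr", "tpr"]] == 1).all()

    def test_one_class_test_set_is_error(self, separable_ts):
        clf = train_model(separable_ts, "random_forest", seed=0)
        one_class = TrainingSet(
            X=separable_ts.X[separable_ts.y == 1].reset_index(drop=True),
            y=separable_ts.y[separable_ts.y == 1],
        )
        with pytest.raises(ValueError):
            evaluate(clf, one_class)


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value, dtype=int)


class TestMlCorrect:
    def _sp(self, n81, n9):
        sp = pd.concat(
            [feature_frame(n81, 60, 0), feature_frame(n9, 60, 1)], ignore_index=True
        )
        sp["phenotype"] = ["CD81_only"] * n81 + ["CD9_only"] * n9
        return sp

    def test_all_predicted_ev_leaves_summary_unchanged(self):
        raw = summarize_counts(50, 40, 100)
        corrected = ml_correct(raw, self._sp(50, 40), _ConstantModel(1))
        for p, f in raw.fractions.items():
            assert corrected.fractions[p] == pytest.approx(f)

    def test_all_predicted_aggregate_gives_dp_one(self):
        raw = summarize_counts(50, 40, 100)
        corrected = ml_correct(raw, self._sp(50, 40), _ConstantModel(0))
        assert corrected.fractions["double_positive"] == pytest.approx(1.0)

    def test_never_increases_single_positive_counts(self):
        raw = summarize_counts(50, 40, 100)
        rng_model = _ConstantModel(1)
        corrected = ml_correct(raw, self._sp(50, 40), rng_model)
        assert corrected.counts["CD81_only"] <= raw.counts["CD81_only"]
        assert corrected.counts["CD9_only"] <= raw.counts["CD9_only"]

    def test_known_contamination_recovered(self):
        # 30% of single positives are planted aggregates with small radii
        dp = feature_frame(200, 60.0, seed=2)
        ab = feature_frame(300, 15.0, seed=3)
        ts = build_training_set(dp, ab)
        clf = train_model(ts, "random_forest", seed=0)
        sp_ev = feature_frame(140, 60.0, seed=4)
        sp_ab = feature_frame(60, 15.0, seed=5)
        sp = pd.concat([sp_ev, sp_ab], ignore_index=True)
        sp["phenotype"] = ["CD81_only"] * 100 + ["CD9_only"] * 100
        raw = summarize_counts(100, 100, 300)
        corrected = ml_correct(raw, sp, clf)
        truth_dp = 300 / (300 + 140)
        assert corrected.fractions["double_positive"] == pytest.approx(truth_dp, abs=0.03)


class TestFeatureImportance:
    def test_label_independent_of_features_all_near_zero(self):
        rng = np.random.default_rng(0)
        X = feature_frame(400, 40.0, seed=6)
        from evpipe.aggregate_classifier import _prepare

        ts = TrainingSet(X=_prepare(X), y=rng.integers(0, 2, 400))
        clf = train_model(ts, "random_forest", seed=0)
        rep = feature_importance(clf, ts, seed=0, n_repeats=5)
        assert rep["importance_mean"].abs().max() < 0.15

    def test_single_informative_feature_ranked_first(self):
        X = feature_frame(400, 40.0, seed=7)
        y = (X["radius_of_gyration"] > np.median(X["radius_of_gyration"])).astype(int)
        # scrub correlated geometry so only rg carries the label
        for col in ("convex_hull_area", "distance_birth", "discretised_area",
                    "distance_depth", "density", "length"):
            X[col] = np.random.default_rng(8).permutation(X[col].to_numpy())
        from evpipe.aggregate_classifier import _prepare

        ts = TrainingSet(X=_prepare(X), y=y.to_numpy())
        clf = train_model(ts, "random_forest", seed=0)
        rep = feature_importance(clf, ts, seed=0, n_repeats=5)
        assert rep.loc[0, "feature"] == "radius_of_gyration"

    def test_deterministic_given_seed(self, separable_ts):
        clf = train_model(separable_ts, "random_forest", seed=0)
        a = feature_importance(clf, separable_ts, seed=3, n_repeats=3)
        b = feature_importance(clf, separable_ts, seed=3, n_repeats=3)
        pd.testing.assert_frame_equal(a, b)
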