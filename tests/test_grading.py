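"""Grading model, ROC/AUC, DeLong test and the repeated-CV protocol."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.feature_selection import SelectKBest, f_classif

from diffnet import (
    FeatureTable,
    GradingModel,
    baseline_selectors,
    cross_validate,
    delong_test,
    fit_logistic,
    roc_auc,
)
from diffnet.grading import classification_metrics, _stratified_folds


def _labelled_table(n=100, p=6, seed=0, signal=0.0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(int)
    X = rng.standard_normal((n, p))
    X[:, 0] += signal * y
    df = pd.DataFrame(X, columns=[f"PX{k}" for k in range(1, p + 1)])
    df["grade"] = y
    return FeatureTable(df)


def _auc_bruteforce(scores, labels):
    """Pair-enumeration oracle: concordant pairs + half ties over all pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (pos.size * neg.size)


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 1, 1, 1], [0, 1, 0, 1], 0.5),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels)["auc"] == pytest.approx(expected)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration(self, seed):
        """AUC equals the brute-force Mann-Whitney count (ties = 1/2)."""
        rng = np.random.default_rng(seed)
        n = 100
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = np.round(rng.standard_normal(n), 1)  # induce ties
        assert roc_auc(scores, labels)["auc"] == pytest.approx(
            _auc_bruteforce(scores, labels)
        )

    def test_confusion_matrix_consistency(self, rng):
        prob = rng.uniform(size=200)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        m = classification_metrics(prob, y)
        pred = (prob >= 0.5).astype(int)
        tp = np.sum((pred == 1) & (y == 1))
        assert m["sensitivity"] == pytest.approx(tp / max(1, (y == 1).sum()))
        assert m["accuracy"] == pytest.approx((pred == y).mean())
        assert m["precision"] == pytest.approx(tp / max(1, (pred == 1).sum()))
        assert all(0 <= m[k] <= 1 for k in m)


class TestGradingModel:
    def test_separable_feature_triggers_ridge_fallback(self):
        table = _labelled_table(n=40)
        df = table.data.copy()
        df["PX1"] = df["grade"].astype(float)
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_logistic(FeatureTable(df), ["PX1"])
        prob = model.predict_proba(df[["PX1"]])[:, 1]
        y = df["grade"].to_numpy()
        assert np.all(prob[y == 1] >= 0.99)
        assert np.all(prob[y == 0] <= 0.01)

    def test_null_training_auc_near_chance(self):
        table = _labelled_table(n=1000, seed=2)
        model = fit_logistic(table, table.feature_columns)
        prob = model.predict_proba(table.X)[:, 1]
        auc = roc_auc(prob, table.grade.to_numpy())["auc"]
        assert 0.45 <= auc <= 0.65

    def test_deterministic_refit(self):
        table = _labelled_table(n=80, signal=1.0, seed=3)
        a = fit_logistic(table, table.feature_columns)
        b = fit_logistic(table, table.feature_columns)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_


class TestDeLong:
    def test_identical_scores(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.standard_normal(50)
        res = delong_test(s, s, y)
        assert res["p"] == 1.0
        assert res["delta"] == 0.0

    def test_perfect_vs_noise(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        perfect = y + 0.0
        noise = rng.standard_normal(n)
        res = delong_test(perfect, noise, y)
        assert res["auc_a"] == 1.0
        assert res["p"] < 0.001

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [1, 2, 3], [0, 1, 1])


class TestCrossValidate:
    def test_fold_sizes_125_into_5(self):
        table = _labelled_table(n=125, signal=2.0)
        report = cross_validate(table, repeats=1, folds=5)
        assert len(report.folds) == 5
        # every validation fold holds exactly 25 samples
        y = table.grade.to_numpy()
        for tr, va in _stratified_folds(y, 5, 0):
            assert va.size == 25

    def test_label_equal_feature_gives_perfect_validation(self):
        table = _labelled_table(n=60)
        df = table.data.copy()
        df["PX1"] = df["grade"].astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cross_validate(FeatureTable(df), features=["PX1"], repeats=1)
        assert report.summary["validation"]["auc"]["mean"] == 1.0

    def test_pure_noise_validation_auc_near_half(self):
        table = _labelled_table(n=200, seed=5)
        report = cross_validate(table, repeats=5, folds=5)
        assert 0.4 <= report.summary["validation"]["auc"]["mean"] <= 0.6

    def test_folds_partition_training_set(self):
        y = (np.arange(125) % 2).astype(int)
        folds = _stratified_folds(y, 5, seed=4)
        all_val = np.sort(np.concatenate([va for _, va in folds]))
        assert np.array_equal(all_val, np.arange(125))

    def test_selector_cannot_see_validation_labels(self):
        """Leakage canary: a feature predictive only on one fold's validation
        rows must not be selected in that fold."""
        n = 100
        table = _labelled_table(n=n, p=4, signal=1.5, seed=8)
        y = table.grade.to_numpy()
        folds = _stratified_folds(y, 5, seed=0)
        canary_rows = folds[0][1]  # validation rows of fold 0
        rng = np.random.default_rng(1)
        canary = rng.standard_normal(n) * 0.1
        canary[canary_rows] = y[canary_rows] * 10.0  # perfect on validation only
        df = table.data.copy()
        df.insert(4, "PX5", canary)
        report = cross_validate(
            FeatureTable(df),
            selector=SelectKBest(f_classif, k=1),
            repeats=1,
            folds=5,
            seeds=[0],
        )
        fold0 = [r for r in report.folds if r["fold"] == 0][0]
        # honest selection sees only training rows, where the canary is noise
        # and PX1 carries real signal; a leaky selection would pick the canary
        assert fold0["features"] == ["PX1"]

    def test_best_fold_has_top_validation_auc(self):
        table = _labelled_table(n=80, signal=1.0, seed=9)
        report = cross_validate(table, repeats=2, folds=4, seeds=[0, 1])
        best = report.best_fold()
        assert best["validation"]["auc"] == max(
            r["validation"]["auc"] for r in report.folds
        )


class TestBaselines:
    @pytest.mark.parametrize("method", ["lasso", "svm-rfe", "random-forest"])
    def test_planted_signal_gives_nonempty_features(self, method):
        table = _labelled_table(n=80, p=8, signal=2.0, seed=4)
        features, report = baseline_selectors(table, method, repeats=1, folds=3)
        assert len(features) > 0
        assert 0 <= report.summary["validation"]["auc"]["mean"] <= 1

    def test_lasso_on_noise_keeps_few_features(self):
        kept = []
        for seed in range(5):
            table = _labelled_table(n=100, p=20, seed=20 + seed)
            features, _ = baseline_selectors(table, "lasso", repeats=1, folds=3, seed=seed)
            kept.append(len(features))
        assert np.median(kept) <= 10  # at most p/2 on pure noise

    def test_deterministic_given_seed(self):
        table = _labelled_table(n=60, p=6, signal=1.0, seed=6)
        f1, r1 = baseline_selectors(table, "random-forest", repeats=1, folds=3, seed=3)
        f2, r2 = baseline_selectors(table, "random-forest", repeats=1, folds=3, seed=3)
        assert f1 == f2
        assert r1.summary == r2.summary
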