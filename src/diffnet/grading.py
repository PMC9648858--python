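"""WHO/ISUP grade classifiers on selected features and their evaluation.

The grading model is an unpenalized logistic regression on the selected
(standardized) features.  Evaluation follows a repeated stratified
cross-validation protocol: 5 repeats of stratified 5-fold CV inside the
training set, with the feature selector re-fit inside every training fold so
that validation folds never leak into selection.  Metrics are AUC (exactly
the Mann-Whitney statistic), precision, sensitivity and accuracy at the 0.5
probability threshold; paired AUCs are compared with the DeLong test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFE
from sklearn.linear_model import LassoCV, LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_is_fitted

from .feature_table import FeatureTable

__all__ = [
    "GradingModel",
    "EvalReport",
    "fit_logistic",
    "cross_validate",
    "roc_auc",
    "delong_test",
    "baseline_selectors",
    "classification_metrics",
]


class GradingModel(ClassifierMixin, BaseEstimator):
    """Logistic grade classifier with internal standardization.

    Maximum-likelihood fit without penalty; if the optimizer fails to
    converge (typically perfect separation), the model falls back to a small
    ridge penalty (strength ``ridge_fallback``) with a warning.

    Attributes
    ----------
    coef_ : ndarray (p,), intercept_ : float
        Coefficients on the standardized feature scale.
    feature_names_ : list or None
    """

    def __init__(self, ridge_fallback: float = 1e-4, max_iter: int = 2000):
        self.ridge_fallback = ridge_fallback
        self.max_iter = max_iter

    def fit(self, X, y, feature_names=None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else feature_names
            X = X.to_numpy(dtype=float)
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("y must be binary")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")
        self.classes_ = classes
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.scale_
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=self.max_iter)
            lr.fit(Z, y)
        margins = Z @ lr.coef_.ravel() + lr.intercept_[0]
        separated = np.all((margins > 0) == (y == self.classes_[1])) and np.all(
            margins != 0
        ) and np.abs(margins).min() > 2.0  # every sample beyond ~0.88 probability
        if separated or any(issubclass(w.category, ConvergenceWarning) for w in caught):
            warnings.warn(
                "perfect separation (or non-convergence) in the unpenalized "
                f"logistic fit; refitting with ridge strength {self.ridge_fallback:g}"
            )
            lr = LogisticRegression(
                C=1.0 / self.ridge_fallback, solver="lbfgs", max_iter=self.max_iter
            )
            lr.fit(Z, y)
        self.coef_ = lr.coef_.ravel()
        self.intercept_ = float(lr.intercept_[0])
        self.feature_names_ = feature_names
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


def fit_logistic(table: FeatureTable, features: list[str]) -> GradingModel:
    """Fit the logistic grading model on a feature subset of a table."""
    X = table.data[list(features)]
    return GradingModel().fit(X, table.grade.to_numpy(), feature_names=list(features))


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> dict:
    """ROC curve and AUC (= Mann-Whitney U / (n1 n0), ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thr,
    }


def classification_metrics(prob, labels, threshold: float = 0.5) -> dict:
    """AUC plus confusion-matrix metrics at the probability threshold."""
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    return {
        "auc": float(roc_auc_score(labels, prob)),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "accuracy": (tp + tn) / labels.size,
    }


def _midrank_components(scores, labels):
    """DeLong structural components (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> dict:
    """DeLong comparison of two correlated AUCs measured on the same samples.

    Returns the two AUCs and the two-sided p-value for their difference.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not scores_a.shape == scores_b.shape == labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if np.unique(labels).size != 2:
        raise ValueError("labels must contain both classes")
    auc_a, v10_a, v01_a = _midrank_components(scores_a, labels)
    auc_b, v10_b, v01_b = _midrank_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    delta = auc_a - auc_b
    if var <= np.finfo(float).tiny:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "delta": float(delta), "p": p}


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class EvalReport:
    """Per-fold records plus summary statistics of a repeated CV evaluation."""

    folds: list  # dicts: repeat, fold, features, train {...}, validation {...}
    summary: dict  # split -> metric -> {"mean", "sd"}
    repeats: int
    n_folds: int

    def best_fold(self) -> dict:
        """Fold record with the highest validation AUC."""
        return max(self.folds, key=lambda r: r["validation"]["auc"])

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "folds": self.n_folds,
            "summary": self.summary,
            "per_fold": self.folds,
        }


def _scores_of(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        s = model.decision_function(X)
        return 1.0 / (1.0 + np.exp(-s))  # squash for thresholding at 0.5
    return np.asarray(model.predict(X), dtype=float)


def _summarize(folds, splits=("train", "validation")):
    summary = {}
    for split in splits:
        summary[split] = {}
        for metric in ("auc", "precision", "sensitivity", "accuracy"):
            vals = np.array([r[split][metric] for r in folds])
            summary[split][metric] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return summary


def cross_validate(
    table: FeatureTable,
    selector=None,
    features: list[str] | None = None,
    estimator=None,
    repeats: int = 5,
    folds: int = 5,
    seeds=None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation inside the training set.

    Each repeat splits the samples into ``folds`` stratified folds; within a
    fold the internal-training part (4/5 by default) is used to re-run the
    selector (if one is given) and fit the classifier, and metrics are
    computed on both the internal-training and the validation part.  With a
    selector, selection never sees validation rows.

    Parameters
    ----------
    selector:
        An sklearn selector (e.g. :class:`DifferentialDegreeSelector`) cloned
        and re-fit per fold, or ``None``.
    features:
        Fixed feature subset (column names) used when no selector is given;
        ``None`` means all feature columns.
    estimator:
        Classifier fit on the (selected) features; default
        :class:`GradingModel`.
    seeds:
        One seed per repeat (default ``0..repeats-1``).
    """
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValueError("need one seed per repeat")
    X_all = table.X.to_numpy(dtype=float)
    y = table.grade.to_numpy()
    columns = table.feature_columns
    records = []
    for r, seed in enumerate(seeds):
        splits = _stratified_folds(y, folds, seed)
        for k, (tr, va) in enumerate(splits):
            if selector is not None:
                sel = clone(selector).fit(X_all[tr], y[tr])
                idx = np.nonzero(sel.get_support())[0]
                feats = [columns[i] for i in idx]
            elif features is not None:
                feats = list(features)
                idx = np.array([columns.index(f) for f in feats])
            else:
                feats = list(columns)
                idx = np.arange(len(columns))
            if idx.size == 0:  # empty selection: predict the majority class
                p_tr = np.full(tr.size, y[tr].mean())
                p_va = np.full(va.size, y[tr].mean())
            else:
                model = clone(estimator) if estimator is not None else GradingModel()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(X_all[np.ix_(tr, idx)], y[tr])
                p_tr = _scores_of(model, X_all[np.ix_(tr, idx)])
                p_va = _scores_of(model, X_all[np.ix_(va, idx)])
            records.append(
                {
                    "repeat": r,
                    "fold": k,
                    "features": feats,
                    "train": classification_metrics(p_tr, y[tr]),
                    "validation": classification_metrics(p_va, y[va]),
                }
            )
    return EvalReport(
        folds=records, summary=_summarize(records), repeats=repeats, n_folds=folds
    )


def _stratified_folds(y, folds, seed, max_attempts: int = 10):
    """Stratified fold indices; re-draw with the next seed if a part is pure."""
    for attempt in range(max_attempts):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        try:
            splits = list(skf.split(np.zeros(len(y)), y))
        except ValueError as exc:
            raise ValueError(f"cannot build {folds} stratified folds: {exc}") from exc
        if all(np.unique(y[tr]).size == 2 and np.unique(y[va]).size == 2 for tr, va in splits):
            return splits
    raise ValueError(
        f"could not build class-balanced folds after {max_attempts} seed attempts"
    )


# ---------------------------------------------------------------------------
# baseline (control) feature-selection models


def _baseline_pipeline(method: str, seed: int):
    if method == "lasso":
        return make_pipeline(
            StandardScaler(), LassoCV(cv=5, random_state=seed)
        )
    if method == "svm-rfe":
        return make_pipeline(
            StandardScaler(), RFE(SVC(kernel="linear", random_state=seed))
        )
    if method == "random-forest":
        return make_pipeline(RandomForestClassifier(random_state=seed))
    raise ValueError(f"unknown baseline method {method!r}")


def _baseline_features(pipe: Pipeline, columns) -> list[str]:
    est = pipe.steps[-1][1]
    if isinstance(est, LassoCV):
        mask = est.coef_ != 0
    elif isinstance(est, RFE):
        mask = est.support_
    else:  # random forest: importance above the mean (SelectFromModel default)
        imp = est.feature_importances_
        mask = imp > imp.mean()
    return [c for c, keep in zip(columns, mask) if keep]


def baseline_selectors(
    table: FeatureTable,
    method: str,
    repeats: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], EvalReport]:
    """Standard wrapper-style control models (library defaults).

    ``method`` is one of ``{"lasso", "svm-rfe", "random-forest"}``.  The
    model is cross-validated with the same repeated stratified protocol as
    the grading model, and the feature subset it retains when fit on the full
    table is returned alongside the report.
    """
    pipe = _baseline_pipeline(method, seed)
    report = cross_validate(
        table, estimator=pipe, repeats=repeats, folds=folds,
        seeds=[seed + r for r in range(repeats)],
    )
    X, y = table.X.to_numpy(dtype=float), table.grade.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = clone(pipe).fit(X, y)
    return _baseline_features(full, table.feature_columns), report
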