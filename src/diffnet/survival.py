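"""Progression-free-survival analysis of the selected radiomics features.

Implements the downstream survival workflow: optimal-cutpoint Kaplan-Meier
with log-rank tests (maximally selected log-rank statistic, as in R's
``surv_cutpoint``), univariate and multivariate Cox proportional-hazards
models (Efron tie handling via lifelines), risk scores, Harrell's C-index,
the Hosmer-Lemeshow calibration test, and a numeric nomogram table mapping
covariate values to points and predicted survival at fixed horizons.

The maximally selected cutpoint p-values reported here are the naive
log-rank p at the chosen cut and are NOT corrected for the selection of the
cut (matching ``surv_cutpoint`` defaults); see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy import stats

from .feature_table import FeatureTable

__all__ = [
    "SurvivalData",
    "CoxFit",
    "optimal_cutpoint",
    "km_logrank",
    "cox_fit",
    "risk_score",
    "c_index",
    "hosmer_lemeshow",
    "nomogram_table",
]


@dataclass
class SurvivalData:
    """Times (months, > 0), event indicators (1 = progression) and covariates."""

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if self.event.sum() == 0:
            raise ValueError("no events observed; survival analysis is degenerate")

    @property
    def n(self) -> int:
        return self.time.size

    @classmethod
    def from_table(cls, table: FeatureTable, features: list[str] | None = None):
        if not table.has_survival:
            raise ValueError("table has no survival columns")
        cov = table.data[list(features)] if features else None
        return cls(
            time=table.data["time_months"].to_numpy(),
            event=table.data["event"].to_numpy(),
            covariates=cov,
        )


# ---------------------------------------------------------------------------
# log-rank machinery


def _logrank_z(group: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E) / sqrt(V) for group 1."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order].astype(bool)
    n = t.size
    num = 0.0
    var = 0.0
    i = 0
    at_risk = n
    at_risk1 = int(g.sum())
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0 and at_risk > 1:
            d1 = int(e[i:j][g[i:j]].sum())
            frac = at_risk1 / at_risk
            num += d1 - d * frac
            var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        at_risk -= j - i
        at_risk1 -= int(g[i:j].sum())
        i = j
    if var <= 0:
        return 0.0
    return num / np.sqrt(var)


def optimal_cutpoint(feature, surv: SurvivalData, minprop: float = 0.1) -> dict:
    """Dichotomization cut maximizing the standardized log-rank statistic.

    Candidate cuts are the observed feature values whose induced split keeps
    at least ``minprop`` of the samples on each side; among those with at
    least one event on each side, the cut with the largest ``|Z|`` wins.
    Returns the cut, the statistic, the (selection-uncorrected) p-value and
    the high/low group indicator (1 where ``feature > cut``).
    """
    x = np.asarray(feature, dtype=float)
    if x.size != surv.n:
        raise ValueError("feature and survival data must have equal length")
    n = x.size
    lo = int(np.ceil(minprop * n))
    values = np.sort(np.unique(x))
    best = None
    for cut in values[:-1]:
        group = (x > cut).astype(int)
        n1 = group.sum()
        if n1 < lo or n - n1 < lo:
            continue
        if surv.event[group == 1].sum() == 0 or surv.event[group == 0].sum() == 0:
            continue
        z = abs(_logrank_z(group, surv.time, surv.event))
        if best is None or z > best[1]:
            best = (float(cut), z, group)
    if best is None:
        raise ValueError("no admissible cut (check minprop and event distribution)")
    cut, z, group = best
    return {
        "cut": cut,
        "statistic": z,
        "p": float(stats.chi2.sf(z**2, df=1)),
        "groups": group,
    }


def km_logrank(groups, surv: SurvivalData) -> dict:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    groups = np.asarray(groups).astype(int)
    curves = {}
    for g in (0, 1):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g} is empty")
        km = KaplanMeierFitter()
        km.fit(surv.time[mask], surv.event[mask], label=f"group{g}")
        curves[g] = km.survival_function_
    res = logrank_test(
        surv.time[groups == 1], surv.time[groups == 0],
        surv.event[groups == 1], surv.event[groups == 0],
    )
    return {"curves": curves, "chi2": float(res.test_statistic), "p": float(res.p_value)}


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """A fitted Cox model: per-covariate HRs, CIs, p-values, and diagnostics."""

    summary: pd.DataFrame  # index: covariate; columns: coef, hr, ci_lower, ci_upper, p
    covariates: list
    log_likelihood: float
    concordance: float
    mean_: np.ndarray
    scale_: np.ndarray
    ranges: pd.DataFrame  # min/max of the (scaled) covariates seen at fit time
    fitter: CoxPHFitter | None = None
    degenerate: list = field(default_factory=list)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.covariates].to_numpy(dtype=float) - self.mean_) / self.scale_
        return Z @ self.summary["coef"].to_numpy()


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()  # Efron ties (lifelines default)
    try:
        cph.fit(df[["time", "event", *covariates]], duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    return cph


def cox_fit(
    surv: SurvivalData,
    covariates: list[str] | None = None,
    mode: str = "multivariate",
    standardize: bool = True,
    screen_alpha: float | None = None,
):
    """Cox proportional-hazards regression on the selected features.

    ``mode="univariate-each"`` fits one single-covariate model per feature
    and returns a list of :class:`CoxFit`; ``mode="multivariate"`` fits one
    joint model.  ``screen_alpha`` applies the univariate -> multivariate
    screening rule: only features with univariate p below the threshold enter
    the multivariate model.

    Zero-variance covariates cannot carry a hazard effect and are reported as
    degenerate (coefficient 0, HR 1) rather than fit.
    """
    if surv.covariates is None:
        raise ValueError("survival data carries no covariates")
    covariates = list(covariates) if covariates is not None else list(surv.covariates.columns)
    X = surv.covariates[covariates].astype(float)
    degenerate = [c for c in covariates if X[c].std(ddof=1) == 0]
    usable = [c for c in covariates if c not in degenerate]
    mean = X[usable].mean().to_numpy()
    if standardize:
        scale = X[usable].std(ddof=1).to_numpy()
    else:
        mean = np.zeros(len(usable))
        scale = np.ones(len(usable))
    Z = pd.DataFrame(
        (X[usable].to_numpy() - mean) / scale, columns=usable, index=X.index
    )
    df = Z.copy()
    df["time"] = surv.time
    df["event"] = surv.event

    def build(fitted: CoxPHFitter, cols: list[str]) -> CoxFit:
        s = fitted.summary
        keep = pd.DataFrame(
            {
                "coef": s["coef"],
                "hr": s["exp(coef)"],
                "ci_lower": s["exp(coef) lower 95%"],
                "ci_upper": s["exp(coef) upper 95%"],
                "p": s["p"],
            }
        )
        for c in degenerate:
            keep.loc[c] = [0.0, 1.0, np.nan, np.nan, np.nan]
        sub = [covariates.index(c) for c in cols]
        ranges = pd.DataFrame(
            {"min": Z[cols].min(), "max": Z[cols].max()}
        )
        return CoxFit(
            summary=keep,
            covariates=cols,
            log_likelihood=float(fitted.log_likelihood_),
            concordance=float(fitted.concordance_index_),
            mean_=mean[[usable.index(c) for c in cols]],
            scale_=scale[[usable.index(c) for c in cols]],
            ranges=ranges,
            fitter=fitted,
            degenerate=degenerate,
        )

    if mode == "univariate-each":
        fits = []
        for c in usable:
            if surv.event.sum() < 6:
                raise ValueError("too few events for a stable univariate Cox fit")
            fits.append(build(_fit_cox(df, [c]), [c]))
        return fits
    if mode != "multivariate":
        raise ValueError("mode must be 'univariate-each' or 'multivariate'")

    selected = usable
    if screen_alpha is not None:
        uni = cox_fit(surv, usable, mode="univariate-each", standardize=standardize)
        selected = [
            f.covariates[0]
            for f in uni
            if float(f.summary.loc[f.covariates[0], "p"]) < screen_alpha
        ]
        if not selected:
            raise ValueError(
                f"no covariate passed the univariate screen at alpha={screen_alpha}"
            )
    if surv.event.sum() < len(selected) + 5:
        raise ValueError(
            f"events ({int(surv.event.sum())}) must exceed covariates "
            f"({len(selected)}) + 5 for a multivariate fit"
        )
    return build(_fit_cox(df, selected), selected)


def risk_score(fit: CoxFit, table: FeatureTable | pd.DataFrame) -> dict:
    """Per-sample risk score (Cox linear predictor) and the rank-ordered panels.

    Returns the scores, a median split into high/low risk, and the numeric
    data behind the standard three-panel risk plot: scores sorted by rank,
    survival time/status by rank, and the (standardized) feature matrix by
    rank.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    scores = fit.linear_predictor(df)
    order = np.argsort(scores, kind="stable")
    split = float(np.median(scores))
    high = (scores > split).astype(int)
    panel = {
        "scores": scores,
        "order": order,
        "risk_group": high,
        "median": split,
    }
    if {"time_months", "event"} <= set(df.columns):
        panel["time"] = df["time_months"].to_numpy()[order]
        panel["status"] = df["event"].to_numpy()[order]
    Z = (df[fit.covariates].to_numpy(dtype=float) - fit.mean_) / fit.scale_
    panel["heatmap"] = pd.DataFrame(
        Z[order], columns=fit.covariates
    )
    return panel


def c_index(scores_or_fit, surv: SurvivalData, table=None) -> float:
    """Harrell's concordance index of a risk score against observed survival.

    Higher scores should predict earlier progression; ties count 1/2 and only
    usable (comparable) pairs enter.
    """
    if isinstance(scores_or_fit, CoxFit):
        if table is None:
            raise ValueError("pass the table the fit should be scored on")
        df = table.data if isinstance(table, FeatureTable) else table
        scores = scores_or_fit.linear_predictor(df)
    else:
        scores = np.asarray(scores_or_fit, dtype=float)
    return float(concordance_index(surv.time, -scores, surv.event))


def hosmer_lemeshow(predicted, observed, bins: int = 10) -> dict:
    """Hosmer-Lemeshow goodness-of-fit chi-square over risk deciles.

    Groups samples into ``bins`` quantile bins of predicted probability and
    compares observed vs expected event counts; the statistic is referred to
    a chi-square with ``bins - 2`` degrees of freedom.  Bins collapse (with a
    warning) when there are fewer distinct predictions than requested bins.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=int)
    if p.shape != y.shape:
        raise ValueError("predicted and observed must have equal length")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("predicted values must be probabilities")
    if np.unique(p).size < bins:
        warnings.warn(
            f"collapsed to {np.unique(p).size} bins "
            f"(fewer distinct predictions than {bins})"
        )
        labels = pd.factorize(p, sort=True)[0]
    else:
        labels = pd.qcut(p, q=bins, labels=False, duplicates="drop")
    g = int(labels.max()) + 1
    if g < 3:
        raise ValueError("need at least 3 distinct risk bins")
    chi2 = 0.0
    for b in range(g):
        mask = labels == b
        n_g = int(mask.sum())
        obs = float(y[mask].sum())
        exp = float(p[mask].sum())
        denom = exp * (1 - exp / n_g)
        if denom <= 0:
            denom = np.finfo(float).eps
        chi2 += (obs - exp) ** 2 / denom
    df = g - 2
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, df=df)), "bins": g}


def nomogram_table(
    fit: CoxFit,
    horizons=(12, 36, 60),
    table: FeatureTable | pd.DataFrame | None = None,
    n_grid: int = 6,
) -> dict:
    """Numeric nomogram: per-covariate points and total-points -> survival.

    Each covariate's contribution ``beta * x`` over its observed range is
    rescaled so the most influential covariate spans 0..100 points; a
    covariate at its reference value (the range end minimizing the hazard)
    scores 0 points.  Total points map linearly back to the Cox linear
    predictor, which gives the predicted survival probability at each
    horizon through the fitted baseline survival.
    """
    beta = fit.summary.loc[fit.covariates, "coef"].to_numpy()
    lo = fit.ranges["min"].to_numpy()
    hi = fit.ranges["max"].to_numpy()
    contrib_lo = np.minimum(beta * lo, beta * hi)
    contrib_hi = np.maximum(beta * lo, beta * hi)
    spans = contrib_hi - contrib_lo
    maxspan = spans.max()
    if maxspan <= 0:
        raise ValueError("all covariates have zero hazard span; nomogram undefined")

    per_covariate = {}
    for k, cov in enumerate(fit.covariates):
        grid = np.linspace(lo[k], hi[k], n_grid)
        points = (beta[k] * grid - contrib_lo[k]) / maxspan * 100.0
        per_covariate[cov] = pd.DataFrame({"value": grid, "points": points})

    if fit.fitter is None:
        raise ValueError("nomogram needs the underlying fitted Cox model")
    base = fit.fitter.baseline_survival_
    base_t = base.index.to_numpy(dtype=float)
    base_s = base.iloc[:, 0].to_numpy(dtype=float)

    def baseline_at(t: float) -> float:
        mask = base_t <= t
        return float(base_s[mask][-1]) if mask.any() else 1.0

    total_max = float(spans.sum() / maxspan * 100.0)
    totals = np.linspace(0.0, total_max, 11)
    rows = []
    for tp in totals:
        lp = tp / 100.0 * maxspan + contrib_lo.sum()
        row = {"total_points": float(tp)}
        for h in horizons:
            row[f"surv_{h}m"] = baseline_at(h) ** np.exp(lp)
        rows.append(row)
    return {
        "per_covariate": per_covariate,
        "total_to_survival": pd.DataFrame(rows),
        "max_total_points": total_max,
        "horizons": tuple(horizons),
    }
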