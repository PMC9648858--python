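"""End-to-end workflow: split -> per-phase selection -> grading CV -> survival.

`run_pipeline` reproduces the experiment shape on any feature table: a
stratified train/test split, differential-network selection per phase (both
the honest per-fold re-selection inside cross-validation and a one-shot
selection on the full training set for the final reported feature set),
choice of the best phase by validation AUC, evaluation on the held-out test
set with DeLong comparisons against baseline models, and the survival
analysis of the winning phase's features.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .feature_table import FeatureTable, stratified_split
from .grading import GradingModel, cross_validate, delong_test, classification_metrics
from .selection import DEFAULT_CAP, DifferentialDegreeSelector, run_all_phases
from .survival import (
    SurvivalData,
    c_index,
    cox_fit,
    hosmer_lemeshow,
    km_logrank,
    nomogram_table,
    optimal_cutpoint,
    risk_score,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("diffnet")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    phases: list[str] | None = None  # None = phases present in the table (+ALL)
    lam: float | str = "auto"
    tau: float = 0.1
    cap: int = DEFAULT_CAP
    test_fraction: float = 50 / 175
    cv_repeats: int = 5
    cv_folds: int = 5
    seed: int = 0
    survival: bool = True
    screen_alpha: float = 0.05
    horizons: tuple[int, ...] = (12, 36, 60)

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cap < 1 or self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("invalid cap / cross-validation settings")
        if self.lam != "auto" and float(self.lam) < 0:
            raise ValueError("lam must be >= 0 or 'auto'")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["horizons"] = list(self.horizons)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "horizons" in d:
            d["horizons"] = tuple(d["horizons"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {"config": config.to_dict(), "config_hash": config.digest(), "seed": config.seed}


def run_pipeline(table: FeatureTable, config: RunConfig | None = None) -> dict:
    """Run the full grading + survival workflow on a labelled feature table.

    Returns a report bundle: ``selection`` (per phase), ``grading``
    (CV summaries, test metrics, DeLong comparisons), and ``survival``
    (KM/log-rank per feature, Cox tables, risk scores, C-index,
    Hosmer-Lemeshow, nomogram), each echoing the config hash and seed.
    """
    config = config or RunConfig()
    t0 = _time.perf_counter()
    split = stratified_split(table, config.test_fraction, seed=config.seed)
    train = table.subset(rows=split.train_idx)
    test = table.subset(rows=split.test_idx)
    log.info("split: %d training / %d test samples", train.n_samples, test.n_samples)

    phases = config.phases
    if phases is None:
        phases = train.phases() or ["ALL"]
        if len(phases) > 1:
            phases = phases + ["ALL"]

    # one-shot selection on the full training set -> final reported features
    selection = run_all_phases(
        train, lam=config.lam, tau=config.tau, cap=config.cap, phases=phases
    )
    log.info("selection: %s", {ph: len(r.selected) for ph, r in selection.items()})

    # honest CV: selector re-fit inside each fold, per phase
    grading: dict = {"per_phase": {}}
    for ph in phases:
        cols = train.phase_columns(ph)
        sub = train.subset(columns=cols)
        selector = DifferentialDegreeSelector(
            lam=config.lam, tau=config.tau, cap=config.cap
        )
        report = cross_validate(
            sub,
            selector=selector,
            repeats=config.cv_repeats,
            folds=config.cv_folds,
            seeds=[config.seed + r for r in range(config.cv_repeats)],
        )
        grading["per_phase"][ph] = report
        log.info(
            "phase %s: validation AUC %.3f",
            ph,
            report.summary["validation"]["auc"]["mean"],
        )

    best_phase = max(
        phases, key=lambda ph: grading["per_phase"][ph].summary["validation"]["auc"]["mean"]
    )
    best_features = list(selection[best_phase].selected)
    grading["best_phase"] = best_phase
    grading["best_features"] = best_features

    y_test = test.grade.to_numpy()
    test_scores: dict[str, np.ndarray] = {}
    if best_features:
        final = GradingModel().fit(
            train.data[best_features], train.grade.to_numpy(), feature_names=best_features
        )
        test_scores[best_phase] = final.predict_proba(test.data[best_features])[:, 1]
        grading["test"] = classification_metrics(test_scores[best_phase], y_test)
    else:
        final = None
        grading["test"] = None

    # DeLong comparison of the remaining phase models on the test set
    delong: dict = {}
    if final is not None:
        for ph in phases:
            if ph == best_phase or not selection[ph].selected:
                continue
            feats = list(selection[ph].selected)
            other = GradingModel().fit(
                train.data[feats], train.grade.to_numpy(), feature_names=feats
            )
            s = other.predict_proba(test.data[feats])[:, 1]
            delong[ph] = delong_test(test_scores[best_phase], s, y_test)
    grading["delong_vs_best"] = delong

    report: dict = {
        **_provenance(config),
        "selection": {ph: r.to_dict() for ph, r in selection.items()},
        "grading": {
            "per_phase": {
                ph: r.to_dict()["summary"] for ph, r in grading["per_phase"].items()
            },
            "best_phase": best_phase,
            "best_features": best_features,
            "test": grading["test"],
            "delong_vs_best": delong,
        },
    }

    if config.survival and table.has_survival and best_features:
        report["survival"] = _survival_report(train, test, best_features, config)

    report["elapsed_s"] = round(_time.perf_counter() - t0, 3)
    return report


def _survival_report(train, test, features, config: RunConfig) -> dict:
    surv_tr = SurvivalData.from_table(train, features=features)
    out: dict = {}

    km: dict = {}
    for f in features:
        try:
            cut = optimal_cutpoint(train.data[f].to_numpy(), surv_tr)
            res = km_logrank(cut["groups"], surv_tr)
            km[f] = {"cut": cut["cut"], "chi2": res["chi2"], "p": res["p"]}
        except ValueError as exc:
            km[f] = {"error": str(exc)}
    out["km_logrank"] = km

    uni = cox_fit(surv_tr, features, mode="univariate-each")
    out["cox_univariate"] = {
        f.covariates[0]: f.summary.loc[f.covariates[0]].to_dict() for f in uni
    }
    try:
        multi = cox_fit(surv_tr, features, mode="multivariate",
                        screen_alpha=config.screen_alpha)
    except (ValueError, RuntimeError) as exc:
        out["cox_multivariate"] = {"error": str(exc)}
        return out
    out["cox_multivariate"] = {
        c: multi.summary.loc[c].to_dict() for c in multi.covariates
    }
    out["c_index_train"] = c_index(multi, surv_tr, table=train)

    rs = risk_score(multi, train)
    out["risk_score"] = {
        "median": rs["median"],
        "events_high_risk": int(train.data["event"].to_numpy()[rs["risk_group"] == 1].sum()),
        "events_low_risk": int(train.data["event"].to_numpy()[rs["risk_group"] == 0].sum()),
    }

    if test.has_survival:
        surv_te = SurvivalData.from_table(test, features=features)
        out["c_index_test"] = c_index(multi, surv_te, table=test)

    # 60-month calibration: predicted progression risk vs observed status,
    # restricted to samples whose 60-month outcome is observable
    horizon = max(config.horizons)
    nomo = nomogram_table(multi, horizons=config.horizons, table=train)
    out["nomogram"] = {
        "max_total_points": nomo["max_total_points"],
        "total_to_survival": nomo["total_to_survival"].to_dict(orient="list"),
    }
    t = surv_tr.time
    e = surv_tr.event
    observable = (t >= horizon) | (e == 1)
    if observable.sum() >= 30:
        lp = multi.linear_predictor(train.data)
        base = nomo["total_to_survival"]
        s_at = _surv_at(multi, horizon)
        pred_risk = 1.0 - s_at ** np.exp(lp[observable])
        obs = ((e == 1) & (t <= horizon)).astype(int)[observable]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["hosmer_lemeshow_60m"] = hosmer_lemeshow(
                np.clip(pred_risk, 0, 1), obs
            )
    return out


def _surv_at(fit, horizon: float) -> float:
    base = fit.fitter.baseline_survival_
    t = base.index.to_numpy(dtype=float)
    s = base.iloc[:, 0].to_numpy(dtype=float)
    mask = t <= horizon
    return float(s[mask][-1]) if mask.any() else 1.0
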