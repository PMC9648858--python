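"""Differential-network feature selection by node degree.

For each contrast phase, a maximum-entropy network is inferred separately
from the high-grade and the low-grade samples; the differential network (the
symmetric difference of the two edge sets) captures which feature
dependencies rewire between grades.  Features are then ranked by their node
degree in the differential network — the count of changed associations —
and the top nodes (fewer than 15 by default) are selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .feature_table import FeatureTable, ValidationError
from .ggm import MaxEntropyNetwork
from .network import DifferentialNetwork, Network, differential

__all__ = [
    "SelectionResult",
    "DifferentialDegreeSelector",
    "group_networks",
    "select_features",
    "run_all_phases",
    "DEFAULT_CAP",
]

#: "fewer than 15" selected features -> cap at 14
DEFAULT_CAP = 14

#: smallest per-grade sample count accepted for covariance estimation
MIN_GROUP_N = 10


@dataclass
class SelectionResult:
    """Ranked differential degrees and the capped selected feature subset."""

    ranking: list  # (feature, degree, strength) sorted best-first, degree >= 1
    selected: list
    cap: int
    phase: str | None = None

    @property
    def degrees(self) -> dict:
        return {f: d for f, d, _ in self.ranking}

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "cap": self.cap,
            "selected": list(self.selected),
            "ranking": [
                {"feature": f, "degree": int(d), "strength": float(s)}
                for f, d, s in self.ranking
            ],
        }


def select_features(
    dnet: DifferentialNetwork,
    cap: int = DEFAULT_CAP,
    phase: str | None = None,
) -> SelectionResult:
    """Rank nodes by differential degree and keep the top ``cap`` of them.

    Only nodes with at least one changed edge are candidates.  Ties in degree
    are broken by the summed ``|delta R|`` of the incident changed edges
    (descending), then by node position (ascending), making the ranking total.
    An empty differential network yields an empty selection with a warning.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    deg = dnet.degrees()
    strength = dnet.strengths()
    pos = {v: k for k, v in enumerate(dnet.nodes)}
    candidates = [v for v in dnet.nodes if deg[v] >= 1]
    candidates.sort(key=lambda v: (-deg[v], -strength[v], pos[v]))
    ranking = [(v, deg[v], strength[v]) for v in candidates]
    selected = candidates[: min(cap, len(candidates))]
    if not selected:
        warnings.warn("differential network is empty; no features selected")
    return SelectionResult(ranking=ranking, selected=selected, cap=cap, phase=phase)


def group_networks(
    table: FeatureTable,
    phase: str = "ALL",
    lam: float | str = "auto",
    tau: float = 0.1,
    min_group_n: int = MIN_GROUP_N,
) -> tuple[Network, Network]:
    """Infer the high-grade and low-grade networks of one phase.

    Each network is estimated only from that grade's samples, restricted to
    the phase's feature columns; features are z-scored within group before
    the covariance, so the two networks share the identical node set but are
    otherwise independent estimates.
    """
    cols = table.phase_columns(phase)
    if not cols:
        raise ValueError(f"no feature columns for phase {phase!r}")
    y = table.grade.to_numpy()
    nets = {}
    for label, tag in ((1, "high"), (0, "low")):
        rows = np.nonzero(y == label)[0]
        if rows.size == 0:
            raise ValidationError(f"no samples with grade={tag!r}")
        if rows.size < min_group_n:
            raise ValidationError(
                f"grade={tag!r} has only {rows.size} samples "
                f"(< {min_group_n}); covariance would be unstable"
            )
        X = table.data.iloc[rows][cols].to_numpy(dtype=float)
        est = MaxEntropyNetwork(lam=lam, tau=tau, standardize=True).fit(X)
        nets[tag] = est.network(nodes=cols, group=tag)
    return nets["high"], nets["low"]


def run_all_phases(
    table: FeatureTable,
    lam: float | str = "auto",
    tau: float = 0.1,
    cap: int = DEFAULT_CAP,
    phases: list[str] | None = None,
) -> dict[str, SelectionResult]:
    """Differential selection for every phase plus the joint all-phase run.

    ``phases`` defaults to the phases present in the table, followed by
    ``"ALL"`` (a single joint network over every feature column) whenever
    more than one phase is present.
    """
    if phases is None:
        phases = table.phases() or ["ALL"]
        if len(phases) > 1:
            phases = list(phases) + ["ALL"]
    out: dict[str, SelectionResult] = {}
    for phase in phases:
        hi, lo = group_networks(table, phase=phase, lam=lam, tau=tau)
        dnet = differential(hi, lo)
        out[phase] = select_features(dnet, cap=cap, phase=phase)
    return out


class DifferentialDegreeSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the differential-degree selection.

    ``fit(X, y)`` splits the samples by the binary label ``y`` (the larger
    label is the high-grade group), infers one maximum-entropy network per
    group, forms their differential network and selects the highest-degree
    nodes.  ``transform`` then keeps the selected columns, so the selector
    composes with sklearn pipelines and cross-validation.

    Parameters
    ----------
    lam : float or "auto", default "auto"
        Precision penalty (EBIC-selected when "auto").
    tau : float, default 0.1
        Partial-correlation threshold defining an edge.
    cap : int, default 14
        Maximum number of selected features (fewer than 15).
    min_group_n : int, default 10
        Smallest acceptable per-group sample count.

    Attributes
    ----------
    support_ : bool ndarray of shape (p,)
    result_ : SelectionResult over integer feature indices
    diffnet_ : DifferentialNetwork
    """

    def __init__(
        self,
        lam: float | str = "auto",
        tau: float = 0.1,
        cap: int = DEFAULT_CAP,
        min_group_n: int = MIN_GROUP_N,
    ):
        self.lam = lam
        self.tau = tau
        self.cap = cap
        self.min_group_n = min_group_n

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("y must contain exactly two classes")
        hi_label = classes.max()
        nets = {}
        for label, tag in ((hi_label, "high"), (classes.min(), "low")):
            rows = y == label
            if rows.sum() < self.min_group_n:
                raise ValueError(
                    f"class {label!r} has {int(rows.sum())} samples "
                    f"(< {self.min_group_n})"
                )
            est = MaxEntropyNetwork(lam=self.lam, tau=self.tau).fit(X[rows])
            nets[tag] = est.network(group=tag)
        self.diffnet_ = differential(nets["high"], nets["low"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.result_ = select_features(self.diffnet_, cap=self.cap)
        self.n_features_in_ = X.shape[1]
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[list(self.result_.selected)] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
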