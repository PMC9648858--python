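"""Maximum-entropy (Gaussian graphical) network inference for one sample group.

For continuous data constrained to match first and second moments, the
maximum-entropy distribution is the multivariate Gaussian
``rho(x) ~ exp(-1/2 x' M x)`` whose interaction matrix ``M`` is the inverse of
the covariance ``C``.  While ``C`` mixes direct and indirect associations,
``M`` (the precision matrix) retains only the conditional dependencies: the
partial correlation between features i and j given all others is

    R_ij = -M_ij / sqrt(M_ii * M_jj).

When the number of features exceeds the number of samples, ``C`` is singular
and ``M`` is estimated by L1-penalized Gaussian maximum likelihood (the
graphical-lasso objective ``log det M - tr(C M) - lambda * ||M||_1,off``),
with the penalty chosen on a log-grid by the extended BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso
from sklearn.utils.validation import check_array, check_is_fitted

from .network import Network

__all__ = [
    "PrecisionModel",
    "MaxEntropyNetwork",
    "sample_covariance",
    "estimate_precision",
    "partial_correlations",
    "to_network",
    "ebic",
]

#: default penalty grid for lambda="auto": 20 points log-spaced in [0.01, 1]
DEFAULT_LAMBDA_GRID = np.logspace(np.log10(0.01), 0.0, 20)

#: condition-number ceiling above which an unpenalized inverse is refused
_MAX_CONDITION = 1e6


@dataclass
class PrecisionModel:
    """Covariance, precision and partial-correlation matrices for one group."""

    covariance: np.ndarray
    precision: np.ndarray
    partial_corr: np.ndarray
    lam: float
    n_samples: int

    @property
    def n_features(self) -> int:
        return self.covariance.shape[0]


def sample_covariance(X, standardize: bool = True) -> np.ndarray:
    """Empirical covariance of an n x p matrix (unbiased, ddof=1).

    With ``standardize`` each column is z-scored first, so the result is the
    correlation matrix (unit diagonal).  A zero-variance column then makes the
    z-score undefined and raises ``ValueError`` naming the column.
    """
    X = check_array(X, dtype=float, ensure_min_samples=2)
    n = X.shape[0]
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            raise ValueError(f"zero-variance column(s) at index {zero.tolist()}")
        Z = (X - X.mean(axis=0)) / sd
        C = Z.T @ Z / (n - 1)
        np.fill_diagonal(C, 1.0)
    else:
        C = np.cov(X, rowvar=False)
        C = np.atleast_2d(C)
    return (C + C.T) / 2.0


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix ``-M_ij / sqrt(M_ii M_jj)`` with zero diagonal."""
    d = np.sqrt(np.diag(precision))
    R = -precision / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    return np.clip(R, -1.0, 1.0)


def ebic(precision: np.ndarray, covariance: np.ndarray, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a Gaussian graphical model.

    ``-2 * loglik + E * log(n) + 4 * gamma * E * log(p)`` where ``E`` counts
    the off-diagonal support pairs.  Smaller is better.
    """
    p = precision.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(covariance @ precision))
    E = int(np.count_nonzero(np.triu(precision, k=1)))
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def _penalized_precision(C: np.ndarray, lam: float) -> tuple[np.ndarray, int]:
    """Graphical-lasso solve; returns (precision, n_iter). Raises on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # iteration-cap warning handled below
        try:
            _, prec, n_iter = graphical_lasso(
                C, alpha=lam, max_iter=200, tol=1e-4, return_n_iter=True
            )
        except FloatingPointError as exc:
            raise RuntimeError(
                f"penalized solver failed at lambda={lam:g}: {exc}"
            ) from exc
    usable = np.all(np.isfinite(prec)) and np.linalg.eigvalsh(prec).min() > 0
    if not usable:
        raise RuntimeError(
            f"penalized solver returned an unusable precision at lambda={lam:g} "
            f"after {n_iter} iterations (tol=1e-4)"
        )
    if n_iter >= 200:
        warnings.warn(
            f"graphical lasso hit the iteration cap at lambda={lam:g} "
            "(duality gap near tolerance); result retained"
        )
    return prec, n_iter


def estimate_precision(C, n: int, lam: float | str = "auto") -> PrecisionModel:
    """Estimate the precision matrix of a group from its covariance.

    Parameters
    ----------
    C:
        Symmetric p x p covariance (or correlation) matrix.
    n:
        Number of samples behind ``C`` (used by the EBIC penalty selection).
    lam:
        ``0`` for the exact inverse (requires a well-conditioned ``C``),
        a positive penalty for the graphical lasso, or ``"auto"`` to pick the
        penalty by EBIC (gamma = 0.5) on a 20-point log grid in [0.01, 1].
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance matrix is not symmetric")
    if n < 2:
        raise ValueError("n must be at least 2")

    if lam == "auto":
        best: tuple[float, np.ndarray, float] | None = None
        for candidate in DEFAULT_LAMBDA_GRID:
            try:
                prec, _ = _penalized_precision(C, float(candidate))
            except RuntimeError:
                continue
            score = ebic(prec, C, n)
            if best is None or score < best[2]:
                best = (float(candidate), prec, score)
        if best is None:
            raise RuntimeError("penalized solver failed on the whole lambda grid")
        lam_used, precision, _ = best
    elif lam == 0:
        cond = np.linalg.cond(C)
        if not np.isfinite(cond) or cond > _MAX_CONDITION:
            raise np.linalg.LinAlgError(
                f"covariance is singular or ill-conditioned (cond={cond:.3g}); "
                "use a positive penalty (lambda > 0) when p approaches n"
            )
        precision = np.linalg.inv(C)
        lam_used = 0.0
    else:
        lam = float(lam)
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        precision, _ = _penalized_precision(C, lam)
        lam_used = lam

    precision = (precision + precision.T) / 2.0
    return PrecisionModel(
        covariance=C,
        precision=precision,
        partial_corr=partial_correlations(precision),
        lam=lam_used,
        n_samples=int(n),
    )


def to_network(model: PrecisionModel, tau: float = 0.1, nodes=None, group=None) -> Network:
    """Threshold the partial-correlation matrix into an undirected network.

    An edge (i, j) is present iff ``|R_ij| >= tau``; its weight is ``|R_ij|``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    R = model.partial_corr
    p = R.shape[0]
    if nodes is None:
        nodes = list(range(p))
    if len(nodes) != p:
        raise ValueError("nodes length must match the matrix dimension")
    iu, ju = np.triu_indices(p, k=1)
    keep = np.abs(R[iu, ju]) >= tau
    edges = {
        (nodes[i], nodes[j]): float(abs(R[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    }
    return Network(nodes=list(nodes), edges=edges, partial_corr=R, group=group, tau=tau)


class MaxEntropyNetwork(BaseEstimator):
    """Scikit-learn style estimator for one group's maximum-entropy network.

    Parameters
    ----------
    lam:
        Precision penalty: 0, a positive float, or ``"auto"`` (EBIC).
    tau:
        Partial-correlation magnitude threshold defining an edge.
    standardize:
        Z-score columns before the covariance (recommended: radiomics
        features live on wildly different scales and the entropy argument is
        scale-free only after standardization).

    Attributes
    ----------
    covariance_, precision_, partial_corr_ : ndarray of shape (p, p)
    lam_ : float
        Penalty actually used (resolved value when ``lam="auto"``).
    network_ : Network
        Thresholded undirected network over integer node labels 0..p-1.
    """

    def __init__(self, lam: float | str = "auto", tau: float = 0.1, standardize: bool = True):
        self.lam = lam
        self.tau = tau
        self.standardize = standardize

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        C = sample_covariance(X, standardize=self.standardize)
        model = estimate_precision(C, n=X.shape[0], lam=self.lam)
        self.n_features_in_ = X.shape[1]
        self.covariance_ = model.covariance
        self.precision_ = model.precision
        self.partial_corr_ = model.partial_corr
        self.lam_ = model.lam
        self.model_ = model
        self.network_ = to_network(model, tau=self.tau)
        return self

    def network(self, tau: float | None = None, nodes=None, group=None) -> Network:
        """Re-threshold the fitted model at a different ``tau`` without refitting."""
        check_is_fitted(self, "model_")
        return to_network(self.model_, tau=self.tau if tau is None else tau,
                          nodes=nodes, group=group)
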