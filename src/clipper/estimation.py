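"""Graph-constrained Gaussian estimation for P >> n.

Two ingredients make whole-pathway likelihoods computable when the gene
count exceeds the sample count: a James-Stein-type shrinkage estimate of the
covariance (always positive definite), and iterative proportional scaling
(IPS) to project that estimate onto the set S+(G) of covariances whose
concentration matrix has zeros off the graph G.

Both are exposed twice: as plain functions (`shrink_covariance`, `ips_fit`,
`ggm_loglik`) and as scikit-learn estimators (`ShrunkenCovariance`,
`GraphConstrainedCovariance`) that compose with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import graphs
from ._kernels import _center, _gauss_ll, _ips, _shrunk_from_centered, cliques_to_arrays

__all__ = [
    "CovarianceEstimate",
    "GGMFit",
    "shrink_covariance",
    "ips_fit",
    "ggm_loglik",
    "ShrunkenCovariance",
    "GraphConstrainedCovariance",
]


@dataclass
class CovarianceEstimate:
    """Shrunken covariance with its estimated intensity and sample count."""

    matrix: np.ndarray
    shrink_lambda: float
    n: int


@dataclass
class GGMFit:
    """Covariance/concentration pair constrained to a graph's zero pattern."""

    graph: nx.Graph
    nodes: list[str]
    sigma: np.ndarray
    concentration: np.ndarray
    converged: bool
    iterations: int
    tolerance_reached: float


def shrink_covariance(X, shrinkage: float | None = None) -> CovarianceEstimate:
    """Shrink the sample covariance toward its diagonal.

    Parameters
    ----------
    X : array-like, shape (n_samples, n_features)
        One class's expression values, samples in rows.
    shrinkage : float in [0, 1], optional
        Override the analytically estimated intensity (0 returns the raw
        unbiased sample covariance, 1 its diagonal).

    Returns lam*diag(S) + (1-lam)*S, positive definite even when the
    feature count exceeds the sample count (provided lam > 0).
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples (rows)")
    var = X.var(axis=0)
    if np.any(var == 0.0):
        bad = list(np.where(var == 0.0)[0])
        raise ValueError(f"zero-variance feature(s) at column(s) {bad}")
    Xc, _ = _center(X)
    S, lam = _shrunk_from_centered(Xc)
    if shrinkage is not None:
        if not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")
        lam = float(shrinkage)
        raw = Xc.T @ Xc / (X.shape[0] - 1)
        S = (1.0 - lam) * raw
        np.fill_diagonal(S, np.diag(raw))
    return CovarianceEstimate(matrix=S, shrink_lambda=float(lam), n=X.shape[0])


def _as_matrix(S) -> np.ndarray:
    if isinstance(S, CovarianceEstimate):
        return S.matrix
    return np.asarray(S, dtype=np.float64)


def ips_fit(
    S,
    g: nx.Graph,
    nodes: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> GGMFit:
    """Project a covariance onto S+(G) by iterative proportional scaling.

    The graph is triangulated if needed and IPS cycles over the maximal
    cliques of the triangulation, matching ``S`` on each clique block; the
    concentration matrix of the result is zero off the (triangulated) graph.

    Parameters
    ----------
    S : CovarianceEstimate or ndarray
        Positive definite start covariance.
    g : undirected graph whose nodes index the rows of ``S``.
    nodes : explicit node order matching the rows of ``S``; defaults to
        sorted(g.nodes).
    """
    Sm = _as_matrix(S)
    if nodes is None:
        nodes = sorted(g.nodes)
    if Sm.shape != (len(nodes), len(nodes)):
        raise ValueError("covariance dimensions do not match graph nodes")
    sign, _ = np.linalg.slogdet(Sm)
    if sign <= 0 or np.min(np.linalg.eigvalsh(Sm)) <= 0:
        raise ValueError("start covariance must be positive definite")
    cg = g if nx.is_chordal(g) else graphs.triangulate(g)
    cliques = graphs.find_cliques(cg)
    node_index = {v: i for i, v in enumerate(nodes)}
    cl_idx, cl_len = cliques_to_arrays(cliques, node_index)
    Sigma, K, it, conv, delta = _ips(
        np.ascontiguousarray(Sm), cl_idx, cl_len, tol, max_iter
    )
    return GGMFit(
        graph=cg,
        nodes=list(nodes),
        sigma=Sigma,
        concentration=K,
        converged=bool(conv),
        iterations=int(it),
        tolerance_reached=float(delta),
    )


def ggm_loglik(fit, S, n: int) -> float:
    """Gaussian profile log-likelihood (n/2)(log det K - tr(K S)).

    The additive -(nP/2) log(2 pi) constant is dropped throughout the
    package; only likelihood differences are ever used.
    """
    K = fit.concentration if isinstance(fit, GGMFit) else np.asarray(fit, float)
    Sm = _as_matrix(S)
    sign, _ = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("concentration matrix must be positive definite")
    return float(_gauss_ll(np.ascontiguousarray(K), np.ascontiguousarray(Sm), n))


class ShrunkenCovariance(BaseEstimator):
    """sklearn-style wrapper around :func:`shrink_covariance`.

    Parameters
    ----------
    shrinkage : float in [0, 1] or None
        Fixed shrinkage intensity; None (default) estimates it analytically.

    Attributes
    ----------
    covariance_ : ndarray (n_features, n_features)
    shrinkage_ : float, intensity actually used
    location_ : ndarray, per-feature mean
    """

    def __init__(self, shrinkage: float | None = None):
        self.shrinkage = shrinkage

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        est = shrink_covariance(X, shrinkage=self.shrinkage)
        self.covariance_ = est.matrix
        self.shrinkage_ = est.shrink_lambda
        self.location_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def get_precision(self):
        check_is_fitted(self, "covariance_")
        return np.linalg.inv(self.covariance_)


class GraphConstrainedCovariance(BaseEstimator):
    """Covariance estimation under a graphical Gaussian model.

    Shrinks the sample covariance, then runs IPS so the precision matrix is
    zero wherever the (triangulated) graph has no edge.

    Parameters
    ----------
    graph : networkx.Graph
        Conditional-independence graph; node names must match feature names
        given in ``nodes`` (or the columns of a DataFrame passed to fit).
    nodes : explicit feature order; defaults to sorted graph nodes.
    shrinkage : optional fixed shrinkage intensity.
    tol, max_iter : IPS stopping rules.

    Attributes
    ----------
    covariance_, precision_ : fitted pair
    shrinkage_ : float
    n_iter_ : IPS sweeps used
    converged_ : bool
    """

    def __init__(
        self,
        graph=None,
        nodes=None,
        shrinkage: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 5000,
    ):
        self.graph = graph
        self.nodes = nodes
        self.shrinkage = shrinkage
        self.tol = tol
        self.max_iter = max_iter

    def _node_order(self, X):
        if self.nodes is not None:
            return list(self.nodes)
        if hasattr(X, "columns"):
            return list(X.columns)
        return sorted(self.graph.nodes)

    def fit(self, X, y=None):
        if self.graph is None:
            raise ValueError("a conditional-independence graph is required")
        nodes = self._node_order(X)
        Xa = np.asarray(X, dtype=np.float64)
        est = shrink_covariance(Xa, shrinkage=self.shrinkage)
        fit = ips_fit(est, self.graph, nodes=nodes, tol=self.tol, max_iter=self.max_iter)
        self.covariance_ = fit.sigma
        self.precision_ = fit.concentration
        self.shrinkage_ = est.shrink_lambda
        self.n_iter_ = fit.iterations
        self.converged_ = fit.converged
        self.feature_names_ = nodes
        self.n_features_in_ = Xa.shape[1]
        self.ggm_fit_ = fit
        return self

    def score(self, X, y=None):
        """Average profile log-likelihood of held-out samples."""
        check_is_fitted(self, "precision_")
        Xa = np.asarray(X, dtype=np.float64)
        Xc, _ = _center(np.ascontiguousarray(Xa))
        S = Xc.T @ Xc / max(Xa.shape[0] - 1, 1)
        return ggm_loglik(self.precision_, S, Xa.shape[0]) / Xa.shape[0]
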