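"""Unsupervised possibilistic fuzzy clustering (UPFC).

UPFC hybridizes fuzzy c-means memberships with possibilistic typicalities:
it minimizes

    J(u, t, C) = sum_ij (a*u_ij^m + b*t_ij^n) * ||x_i - c_j||^2
               + beta / (n^2 * sqrt(N_C)) * sum_ij (t_ij^n * log t_ij^n - t_ij^n)

subject to each membership row summing to one.  The memberships pull
centroids like FCM; the exponential typicalities discount outliers like a
possibilistic method; the entropy term keeps typicalities from collapsing
to zero.  Setting b = 0 recovers a pure membership-driven run (t becomes
identically 1 and drops out of the centroid weights).

beta is the sample variance of distances to the data mean and sets the
length scale of the typicality exponential:

    t_ij = exp(-(b * n * sqrt(N_C) / beta) * ||x_i - c_j||^2),

which is the stationary point of J in t for the entropy coefficient above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class UPFCParams:
    """Tuning knobs of the clustering objective.

    m, n > 1 are the fuzzifier and typicality exponents; a, b >= 0 weight
    the membership and typicality terms (a > 0 required).  Defaults are
    m = n = 1.5, a = b = 0.5.
    """

    m: float = 1.5
    n: float = 1.5
    a: float = 0.5
    b: float = 0.5
    max_iter: int = 300
    tol: float = 1e-5

    def __post_init__(self):
        if self.m <= 1 or self.n <= 1:
            raise ValueError("fuzzifier m and typicality n must exceed 1")
        if self.a <= 0 or self.b < 0:
            raise ValueError("require a > 0 and b >= 0")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be positive and tol > 0")


@dataclass
class UPFCResult:
    centroids: np.ndarray          # (N_C, p)
    u_fcm: np.ndarray              # (N_S, N_C) memberships, rows sum to 1
    u_pca: np.ndarray              # (N_S, N_C) typicalities in (0, 1]
    beta: float
    n_iter: int
    objective: float
    objective_trace: list = field(default_factory=list)
    data_term_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_clusters": int(self.centroids.shape[0]),
            "beta": float(self.beta),
            "n_iter": int(self.n_iter),
            "objective": float(self.objective),
        }


def compute_beta(X) -> float:
    """Sample variance of distances to the data mean (separation scale).

    beta = (1/N_S) * sum_i ||x_i - x_avg||^2.  A value of 0 (all samples
    identical) is returned but logged; the typicality update rejects it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("need at least one sample")
    beta = float(np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1)))
    if beta == 0.0:
        logger.warning("degenerate data: all samples identical (beta = 0)")
    return beta


def _sq_distances(X, centroids) -> np.ndarray:
    return cdist(np.atleast_2d(X), np.atleast_2d(centroids), "sqeuclidean")


def update_fcm_memberships(X, centroids, m: float) -> np.ndarray:
    """Fuzzy membership update: u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1)).

    A sample coinciding with one or more centroids splits membership 1
    equally among the coincident centroids.  Duplicate centroids are
    permitted (coincident-cluster hazard) but logged.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    centroids = np.atleast_2d(centroids)
    if len(centroids) > 1 and len(np.unique(centroids, axis=0)) < len(centroids):
        # coincident-cluster hazard; frequent in possibilistic regimes
        logger.debug("duplicate centroids detected (coincident clusters)")
    d2 = _sq_distances(X, centroids)
    zero = d2 == 0.0
    u = np.zeros_like(d2)
    singular = zero.any(axis=1)
    if singular.any():
        z = zero[singular]
        u[singular] = z / z.sum(axis=1, keepdims=True)
    regular = ~singular
    if regular.any():
        w = d2[regular] ** (-1.0 / (m - 1.0))
        u[regular] = w / w.sum(axis=1, keepdims=True)
    return u


def update_pca_typicalities(X, centroids, beta: float, params: UPFCParams) -> np.ndarray:
    """Possibilistic typicality update t_ij = exp(-(b*n*sqrt(N_C)/beta) d_ij^2)."""
    if beta <= 0:
        raise ValueError("beta must be positive (degenerate data?)")
    d2 = _sq_distances(X, centroids)
    n_clusters = np.atleast_2d(centroids).shape[0]
    return np.exp(-(params.b * params.n * np.sqrt(n_clusters) / beta) * d2)


def _centroid_weights(u_fcm, u_pca, params: UPFCParams) -> np.ndarray:
    return params.a * u_fcm ** params.m + params.b * u_pca ** params.n


def update_centroids(X, u_fcm, u_pca, params: UPFCParams, prev_centroids=None) -> np.ndarray:
    """Weighted-mean centroid update with weights a*u^m + b*t^n.

    A cluster whose weights sum to zero keeps its previous centroid (if
    given) and a warning is logged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    w = _centroid_weights(np.asarray(u_fcm), np.asarray(u_pca), params)
    totals = w.sum(axis=0)
    dead = totals == 0.0
    if dead.any():
        logger.debug("%d cluster(s) received zero total weight", int(dead.sum()))
        totals = np.where(dead, 1.0, totals)
    centroids = (w.T @ X) / totals[:, None]
    if dead.any():
        if prev_centroids is None:
            raise ValueError("zero-weight cluster and no previous centroid to keep")
        centroids[dead] = np.atleast_2d(prev_centroids)[dead]
    return centroids


def _objective(X, centroids, u_fcm, u_pca, params: UPFCParams, beta: float):
    d2 = _sq_distances(X, centroids)
    data_term = float((_centroid_weights(u_fcm, u_pca, params) * d2).sum())
    tn = u_pca ** params.n
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(tn > 0.0, tn * np.log(np.where(tn > 0.0, tn, 1.0)) - tn, 0.0)
    n_clusters = centroids.shape[0]
    entropy_term = float(beta / (params.n ** 2 * np.sqrt(n_clusters)) * ent.sum())
    return data_term + entropy_term, data_term


def run_upfc(X, n_clusters: int, params: UPFCParams | None = None, seed=None) -> UPFCResult:
    """Iterate membership/typicality/centroid updates to convergence.

    Centroids start as a seeded random sample of distinct data points and
    the loop stops when the maximum centroid displacement drops below
    ``params.tol`` or after ``params.max_iter`` sweeps.
    """
    params = params or UPFCParams()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n_samples = X.shape[0]
    if not 1 <= n_clusters < n_samples:
        raise ValueError(
            f"n_clusters must satisfy 1 <= n_clusters < n_samples ({n_clusters} vs {n_samples})"
        )
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n_samples, size=n_clusters, replace=False)].copy()
    beta = compute_beta(X)
    if beta <= 0:
        raise ValueError("degenerate data: beta = 0, typicalities undefined")

    obj_trace, data_trace = [], []
    u = t = None
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        u = update_fcm_memberships(X, centroids, params.m)
        t = update_pca_typicalities(X, centroids, beta, params)
        new_centroids = update_centroids(X, u, t, params, prev_centroids=centroids)
        shift = float(np.max(np.linalg.norm(new_centroids - centroids, axis=1)))
        centroids = new_centroids
        obj, data_term = _objective(X, centroids, u, t, params, beta)
        obj_trace.append(obj)
        data_trace.append(data_term)
        if shift < params.tol:
            break

    return UPFCResult(
        centroids=centroids,
        u_fcm=u,
        u_pca=t,
        beta=beta,
        n_iter=n_iter,
        objective=obj_trace[-1],
        objective_trace=obj_trace,
        data_term_trace=data_trace,
    )
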