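"""Fuzzy k-nearest-neighbor classification against labeled prototypes.

Class memberships are distance-weighted votes among the k nearest
prototypes:

    u_i(x) = sum_j u_ij * w_j / sum_j w_j,   w_j = ||x - x_j||^(-2/(m-1)),

with u_ij the crisp indicator of prototype j belonging to class i, so the
memberships form a convex combination of indicators and sum to one.  The
scale exponent m defaults to 1.5 (weight w = d^-4).  A query coinciding
with prototypes gives membership 1 split equally over the coincident
prototypes' classes.  Ties in the final argmax break by the fixed class
order white < yellow < opaque < brown < background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .labels import CLASS_NAMES
from .prototypes import PrototypeSet

N_CLASSES = len(CLASS_NAMES)


@dataclass
class FknnConfig:
    k: int = 1
    m_scale: float = 1.5

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m_scale <= 1:
            raise ValueError("m_scale must exceed 1")


def fknn_memberships_batch(X, prototypes: PrototypeSet, cfg: FknnConfig | None = None) -> np.ndarray:
    """Per-class membership vectors, one row per query, columns in class order."""
    cfg = cfg or FknnConfig()
    if len(prototypes) == 0:
        raise ValueError("empty prototype set")
    k = min(cfg.k, len(prototypes))
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    tree = cKDTree(prototypes.centroids)
    dist, idx = tree.query(X, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    neighbor_labels = prototypes.labels[idx]

    u = np.zeros((X.shape[0], N_CLASSES))
    coincident = dist[:, 0] == 0.0
    if coincident.any():
        # exact hits: split membership 1 equally over ALL zero-distance
        # prototypes, which may exceed the k returned by the tree
        for row in np.flatnonzero(coincident):
            hits = tree.query_ball_point(X[row], r=0.0)
            hit_labels = prototypes.labels[np.asarray(hits, dtype=np.intp)]
            counts = np.bincount(hit_labels, minlength=N_CLASSES)
            u[row] = counts / counts.sum()
    regular = ~coincident
    if regular.any():
        w = dist[regular] ** (-2.0 / (cfg.m_scale - 1.0))
        labels_r = neighbor_labels[regular]
        for c in range(N_CLASSES):
            u[regular, c] = np.where(labels_r == c, w, 0.0).sum(axis=1)
        u[regular] /= w.sum(axis=1, keepdims=True)
    return u


def fknn_memberships(x, prototypes: PrototypeSet, cfg: FknnConfig | None = None) -> dict:
    """Class-name -> membership map for a single feature vector."""
    u = fknn_memberships_batch(np.atleast_2d(x), prototypes, cfg)[0]
    return {name: float(v) for name, v in zip(CLASS_NAMES, u)}


def classify_batch(X, prototypes: PrototypeSet, cfg: FknnConfig | None = None) -> np.ndarray:
    """Vectorized argmax classification; returns int class codes."""
    u = fknn_memberships_batch(X, prototypes, cfg)
    return np.argmax(u, axis=1)  # first max wins = fixed label order


def classify(x, prototypes: PrototypeSet, cfg: FknnConfig | None = None) -> int:
    return int(classify_batch(np.atleast_2d(x), prototypes, cfg)[0])
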