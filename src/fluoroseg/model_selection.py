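"""Cuckoo-search model selection for the number of clusters.

Each nest holds a candidate cluster count eta.  A nest's fitness is the
squared gap (y - y_hat)^2 between the validation accuracy y obtained by
training UPFC with eta clusters (clusters labeled by majority vote,
validation pixels classified by FKNN with k = 1) and an expected accuracy
y_hat.  Nests are perturbed by Mantegna Levy-flight steps, a cuckoo
replaces a randomly chosen nest when its fitness is better, and each
generation every non-best nest is abandoned and rebuilt with probability
p_a.  The best solution is retained across generations (elitism).

Cross-validation follows the study protocol: ONE fold trains, the
remaining folds validate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as gamma_fn

from .fknn import FknnConfig, classify_batch
from .labels import CLASS_NAMES
from .prototypes import PrototypeSet
from .upfc import UPFCParams, UPFCResult, run_upfc

logger = logging.getLogger(__name__)

_SEED_MOD = 2 ** 31


@dataclass
class Nest:
    eta: int
    fitness: float = math.inf


@dataclass
class CSConfig:
    """Cuckoo-search settings.

    Defaults are the full-scale study configuration: 30 nests searching
    cluster counts in [1000, 2500] toward an expected accuracy of 0.99,
    step scale alpha = 0.1, Levy exponent 1.5, discovery probability 0.25,
    tolerance 0.001, at most 100 generations.
    """

    n_nests: int = 30
    bounds: tuple = (1000, 2500)
    y_hat: float = 0.99
    alpha: float = 0.1
    beta_levy: float = 1.5
    p_a: float = 0.25
    eps: float = 0.001
    t_max: int = 100
    seed: int | None = None

    def __post_init__(self):
        lo, hi = self.bounds
        if not (0 < self.beta_levy <= 2):
            raise ValueError("Levy exponent must lie in (0, 2]")
        if not (0 <= self.p_a <= 1):
            raise ValueError("p_a must lie in [0, 1]")
        if lo > hi or lo < 1:
            raise ValueError("invalid cluster-count bounds")


@dataclass
class CSResult:
    prototypes: PrototypeSet | None
    best_eta: int
    best_fitness: float
    accuracy: float | None
    trace: list = field(default_factory=list)  # dicts: generation, best_eta, best_fitness, n_rebuilt

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(self.trace)


def levy_sigma_u(beta_levy: float) -> float:
    """Mantegna scale sigma_u; sigma_v is 1 for every exponent."""
    num = gamma_fn(1.0 + beta_levy) * math.sin(math.pi * beta_levy / 2.0)
    den = gamma_fn((1.0 + beta_levy) / 2.0) * beta_levy * 2.0 ** ((beta_levy - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta_levy)


def levy_step(shape, beta_levy: float, rng) -> np.ndarray:
    """Heavy-tailed Levy draw s = u / |v|^(1/beta), Mantegna's algorithm."""
    if not (0 < beta_levy <= 2):
        raise ValueError("Levy exponent must lie in (0, 2]")
    u = rng.normal(0.0, levy_sigma_u(beta_levy), size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    return u / np.abs(v) ** (1.0 / beta_levy)


def propose_cuckoo(nest: Nest, best: Nest, cfg: CSConfig, rng) -> Nest:
    """Levy-flight proposal, rounded and clamped to the integer bounds.

    Step s = alpha * (eta - eta_best) * Levy(beta); the best nest itself
    moves by a pure alpha-scaled Levy draw so the search never freezes.
    """
    lev = float(levy_step((), cfg.beta_levy, rng))
    if nest.eta == best.eta:
        s = cfg.alpha * lev
    else:
        s = cfg.alpha * (nest.eta - best.eta) * lev
    lo, hi = cfg.bounds
    eta = int(np.clip(round(nest.eta + s), lo, hi))
    return Nest(eta=eta)


def fitness_from_accuracy(accuracy: float, y_hat: float) -> float:
    """Squared-error nest fitness (y - y_hat)^2."""
    return float((accuracy - y_hat) ** 2)


def label_clusters(result, X, y) -> PrototypeSet:
    """Attach one majority-vote class label to every centroid.

    Each training pixel votes for its nearest centroid; ties break by the
    fixed class order; empty clusters inherit the label of the nearest
    non-empty centroid.
    """
    centroids = result.centroids if isinstance(result, UPFCResult) else np.atleast_2d(result)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.intp)
    from scipy.spatial import cKDTree

    tree = cKDTree(centroids)
    _, assign = tree.query(X, k=1)
    n_clusters = centroids.shape[0]
    votes = np.zeros((n_clusters, len(CLASS_NAMES)), dtype=np.int64)
    np.add.at(votes, (assign, y), 1)
    occupied = votes.sum(axis=1) > 0
    labels = np.argmax(votes, axis=1)  # first max = fixed label order
    if not occupied.all():
        occ_idx = np.flatnonzero(occupied)
        if occ_idx.size == 0:
            raise ValueError("no training pixels to label clusters with")
        from scipy.spatial.distance import cdist

        d = cdist(centroids[~occupied], centroids[occ_idx])
        labels[~occupied] = labels[occ_idx[np.argmin(d, axis=1)]]
    return PrototypeSet(centroids, labels)


def nest_fitness(eta, X_train, y_train, X_val, y_val, params: UPFCParams,
                 y_hat: float, seed) -> tuple:
    """Train/label/validate one candidate cluster count.

    Returns (fitness, (PrototypeSet, accuracy)).  eta is clamped below the
    training-sample count when necessary (logged).
    """
    n_train = len(X_train)
    eta_eff = int(eta)
    if eta_eff >= n_train:
        logger.warning("eta=%d >= %d training samples; clamping", eta_eff, n_train)
        eta_eff = n_train - 1
    result = run_upfc(X_train, eta_eff, params, seed=seed)
    protos = label_clusters(result, X_train, y_train)
    pred = classify_batch(X_val, protos, FknnConfig(k=1))
    accuracy = float(np.mean(pred == np.asarray(y_val)))
    return fitness_from_accuracy(accuracy, y_hat), (protos, accuracy)


def _eval_seed(base_seed, nest_id, generation) -> int:
    ss = np.random.SeedSequence([0 if base_seed is None else int(base_seed),
                                 int(nest_id), int(generation)])
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def minimize_cuckoo(fitness_fn, cfg: CSConfig) -> CSResult:
    """Generic cuckoo-search loop over integer cluster counts.

    ``fitness_fn(eta, eval_seed) -> (fitness, payload)``; the payload of
    the best evaluation ever seen is kept (trained centroids are cached
    rather than recomputed).  Stops when the best fitness falls below
    cfg.eps or after cfg.t_max generations.
    """
    lo, hi = cfg.bounds
    rng = np.random.default_rng(cfg.seed)
    etas = rng.integers(lo, hi + 1, size=cfg.n_nests).astype(int)

    best = {"eta": None, "fitness": math.inf, "payload": None}

    def evaluate(i, eta, generation):
        f, payload = fitness_fn(int(eta), _eval_seed(cfg.seed, i, generation))
        if f < best["fitness"]:
            best.update(eta=int(eta), fitness=f, payload=payload)
        return f

    fitness = np.array([evaluate(i, e, 0) for i, e in enumerate(etas)])
    trace = [{"generation": 0, "best_eta": best["eta"],
              "best_fitness": best["fitness"], "n_rebuilt": 0}]

    for t in range(1, cfg.t_max + 1):
        if best["fitness"] < cfg.eps:
            break
        best_nest = Nest(best["eta"], best["fitness"])
        for i in range(cfg.n_nests):
            cuckoo = propose_cuckoo(Nest(etas[i], fitness[i]), best_nest, cfg, rng)
            f_new = evaluate(i, cuckoo.eta, t)
            j = int(rng.integers(cfg.n_nests))
            if f_new < fitness[j]:
                etas[j], fitness[j] = cuckoo.eta, f_new
        # abandonment: every non-best nest is rebuilt with probability p_a
        protect = int(np.argmin(fitness))
        n_rebuilt = 0
        for i in range(cfg.n_nests):
            if i == protect:
                continue
            if rng.random() < cfg.p_a:
                etas[i] = int(rng.integers(lo, hi + 1))
                fitness[i] = evaluate(i, etas[i], t + cfg.t_max + 1)
                n_rebuilt += 1
        trace.append({"generation": t, "best_eta": best["eta"],
                      "best_fitness": best["fitness"], "n_rebuilt": n_rebuilt})

    payload = best["payload"]
    protos, acc = (payload if isinstance(payload, tuple) else (None, None))
    if isinstance(protos, PrototypeSet):
        protos.metadata.update(eta=best["eta"], fitness=best["fitness"], accuracy=acc)
    return CSResult(prototypes=protos if isinstance(protos, PrototypeSet) else None,
                    best_eta=best["eta"], best_fitness=best["fitness"],
                    accuracy=acc, trace=trace)


def run_cuckoo_search(X, y, cfg: CSConfig, params: UPFCParams | None = None,
                      val_data=None) -> CSResult:
    """Optimize the cluster count on labeled pixels and return the trained model.

    When ``val_data`` is None the pixels are split per the study protocol:
    one tenth trains and the remaining nine tenths validate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.intp)
    if X.shape[0] == 0:
        raise ValueError("empty pixel set")
    if np.unique(y).size < 2:
        raise ValueError("need labeled pixels from at least 2 classes")
    params = params or UPFCParams()

    if val_data is None:
        rng = np.random.default_rng(cfg.seed)
        perm = rng.permutation(X.shape[0])
        n_train = max(2, X.shape[0] // 10)
        tr, va = perm[:n_train], perm[n_train:]
        X_train, y_train, X_val, y_val = X[tr], y[tr], X[va], y[va]
    else:
        X_train, y_train = X, y
        X_val, y_val = val_data
        X_val = np.atleast_2d(np.asarray(X_val, dtype=np.float64))
        y_val = np.asarray(y_val, dtype=np.intp)

    def fitness_fn(eta, eval_seed):
        return nest_fitness(eta, X_train, y_train, X_val, y_val, params,
                            cfg.y_hat, eval_seed)

    return minimize_cuckoo(fitness_fn, cfg)


@dataclass
class CVResult:
    fold_accuracies: list
    best_prototypes: PrototypeSet
    best_fold: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(X, y, cfg: CSConfig, params: UPFCParams | None = None,
                   k_folds: int = 10) -> CVResult:
    """k-fold protocol with the study's inverted direction.

    The data are partitioned into k folds (sizes differing by at most 1);
    for each fold the cuckoo search trains on THAT fold and validates on
    the union of the others.  Returns per-fold accuracies and the
    prototype set of the best fold.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.intp)
    rng = np.random.default_rng(cfg.seed)
    folds = np.array_split(rng.permutation(X.shape[0]), k_folds)

    accuracies, models = [], []
    n_classes = np.unique(y).size
    for f, fold_idx in enumerate(folds):
        rest = np.concatenate([folds[g] for g in range(k_folds) if g != f])
        if np.unique(y[fold_idx]).size < n_classes:
            logger.warning("fold %d is missing at least one class", f)
        fold_cfg = replace(cfg, seed=_eval_seed(cfg.seed, 104729, f))
        res = run_cuckoo_search(X[fold_idx], y[fold_idx], fold_cfg, params,
                                val_data=(X[rest], y[rest]))
        accuracies.append(res.accuracy)
        models.append(res.prototypes)
    best_fold = int(np.argmax(accuracies))
    best = models[best_fold]
    best.metadata.update(fold=best_fold, fold_accuracies=[float(a) for a in accuracies])
    return CVResult(fold_accuracies=[float(a) for a in accuracies],
                    best_prototypes=best, best_fold=best_fold)
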