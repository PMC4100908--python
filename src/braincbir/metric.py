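"""Rank-error metric learning (REML) with an LFDA initializer.

Retrieval similarity is the squared Mahalanobis distance d(x_i, x_j) =
‖L(x_i − x_j)‖² with a learned d×D projection L.  For a query q with relevant
set S and irrelevant set D (same-class vs other-class items), the rank error
counts relevant items ranked below some irrelevant item.  Both
non-smooth pieces are smoothed:

* the hardest-irrelevant gap  g_i = max_{j∈D}(d_i − d_j)  becomes the
  log-sum-exp  g̃_i = (1/η)·ln Σ_{j∈D} exp(η·(d_i − d_j));
* the 0/1 indicator becomes the logistic (softplus) loss ln(1 + exp(g̃_i)).

The per-query loss is Σ_{i∈S} ln(1 + exp(g̃_i)); the objective averages it
over queries and adds γ·tr(LᵀL) (= γ‖L‖_F²).  Optimization is stochastic
gradient descent from an LFDA initialization, keeping the iterate with the
lowest monitored objective.  LFDA (local Fisher discriminant analysis) solves
the generalized eigenproblem of the locality-weighted between-/within-class
scatter pair; the affinity uses local-scaling weights with the 7th nearest
neighbor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist
from scipy.special import expit, logsumexp

from .errors import BrainCBIRError


@dataclass
class MetricProjection:
    """d×D linear map defining the learned squared Mahalanobis distance."""

    L: np.ndarray

    @property
    def d(self) -> int:
        return self.L.shape[0]

    @property
    def D(self) -> int:
        return self.L.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.L.T

    def save(self, path: str | Path, config_echo: dict | None = None,
             log: dict | None = None) -> None:
        payload = {
            "d": int(self.d),
            "D": int(self.D),
            "config": config_echo or {},
            "log": log or {},
            "L": np.asarray(self.L, dtype=float).ravel().tolist(),  # row-major
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MetricProjection":
        payload = json.loads(Path(path).read_text())
        return cls(L=np.asarray(payload["L"]).reshape(payload["d"], payload["D"]))


@dataclass
class QueryRelevance:
    """One query feature against a database with 0/1 relevance flags."""

    x_q: np.ndarray
    X_db: np.ndarray
    rel: np.ndarray  # bool, 1 = relevant (set S), 0 = irrelevant (set D)

    def __post_init__(self):
        self.x_q = np.asarray(self.x_q, dtype=float)
        self.X_db = np.atleast_2d(np.asarray(self.X_db, dtype=float))
        self.rel = np.asarray(self.rel, dtype=bool)
        if self.rel.shape[0] != self.X_db.shape[0]:
            raise ValueError("one relevance flag per database item required")

    @property
    def trainable(self) -> bool:
        return bool(self.rel.any() and (~self.rel).any())


@dataclass(frozen=True)
class REMLConfig:
    gamma: float = 1e-4
    eta: float = 1.0
    t_max: int = 1000
    d: int = 3
    seed: int = 0
    monitor_interval: int = 50
    alpha_scale: float = 1e-3
    lfda_knn: int = 7

    def __post_init__(self):
        if self.gamma < 0 or self.eta <= 0 or self.t_max < 1 or self.d < 1:
            raise ValueError("invalid REML configuration")


def mahalanobis_sq(L: MetricProjection | np.ndarray, x_i, x_j) -> float:
    """‖L(x_i − x_j)‖²."""
    mat = L.L if isinstance(L, MetricProjection) else np.asarray(L, dtype=float)
    diff = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
    v = mat @ diff
    return float(v @ v)


def _distances(L: np.ndarray, query: QueryRelevance) -> np.ndarray:
    proj_diff = (query.X_db - query.x_q) @ L.T
    return np.einsum("ij,ij->i", proj_diff, proj_diff)


def smoothed_gaps(L: MetricProjection | np.ndarray, query: QueryRelevance,
                  eta: float = 1.0) -> np.ndarray:
    """Log-sum-exp smoothed distance gaps g̃_i for every relevant item i.

    g̃_i = d_i + (1/η)·ln Σ_{j∈D} exp(−η·d_j), evaluated with a max-shift;
    g̃_i → max_{j∈D}(d_i − d_j) as η → ∞, and equals the hard gap exactly
    when |D| = 1.
    """
    mat = L.L if isinstance(L, MetricProjection) else np.asarray(L, dtype=float)
    dist = _distances(mat, query)
    dD = dist[~query.rel]
    if dD.size == 0:
        raise ValueError("query has no irrelevant items")
    lse = logsumexp(-eta * dD)
    return dist[query.rel] + lse / eta


def smoothed_gap(L, query: QueryRelevance, i: int, eta: float = 1.0) -> float:
    """g̃ for the i-th relevant item (i indexes the relevant subset in order)."""
    return float(smoothed_gaps(L, query, eta)[i])


def reml_loss(L, query: QueryRelevance, config: REMLConfig = REMLConfig()) -> float:
    """Per-query smoothed rank-error loss Σ_{i∈S} ln(1 + exp(g̃_i))."""
    if not query.trainable:
        warnings.warn("query skipped: relevant or irrelevant set empty")
        return 0.0
    g = smoothed_gaps(L, query, config.eta)
    return float(np.logaddexp(0.0, g).sum())


def reml_objective(L, queries: list[QueryRelevance],
                   config: REMLConfig = REMLConfig()) -> float:
    """Mean per-query loss + γ·tr(LᵀL)."""
    mat = L.L if isinstance(L, MetricProjection) else np.asarray(L, dtype=float)
    usable = [q for q in queries if q.trainable]
    if not usable:
        raise ValueError("no trainable query")
    loss = float(np.mean([reml_loss(mat, q, config) for q in usable]))
    return loss + config.gamma * float(np.sum(mat * mat))


def reml_gradient(L, query: QueryRelevance,
                  config: REMLConfig = REMLConfig()) -> np.ndarray:
    """Analytic gradient of reml_loss + γ-regularizer w.r.t. L.

    Chain rule through the softplus, the log-sum-exp and the pairwise
    distances ∂d_j/∂L = 2·L·(x_q − x_j)(x_q − x_j)ᵀ.  Because the log-sum-exp
    weights softmax(−η·d_j) do not depend on the relevant item, the gradient
    collapses to one weighted outer-product sum over database items.
    """
    mat = L.L if isinstance(L, MetricProjection) else np.asarray(L, dtype=float)
    if not query.trainable:
        return 2.0 * config.gamma * mat
    eta = config.eta
    U = query.X_db - query.x_q
    P = U @ mat.T
    dist = np.einsum("ij,ij->i", P, P)
    relm = query.rel
    dD = dist[~relm]
    lse = logsumexp(-eta * dD)
    w = np.exp(-eta * dD - lse)  # softmax over the irrelevant set
    g = dist[relm] + lse / eta
    s = expit(g)  # dloss/dg̃_i
    coeff = np.zeros(dist.shape[0])
    coeff[relm] = s
    coeff[~relm] = -s.sum() * w
    grad = 2.0 * (P * coeff[:, None]).T @ U
    return grad + 2.0 * config.gamma * mat


# ---------------------------------------------------------------------------
# LFDA initialization


def lfda_fit(X: np.ndarray, y: np.ndarray, d: int, knn: int = 7) -> MetricProjection:
    """Local Fisher discriminant analysis projection (rows = top-d eigenvectors).

    Scatter matrices use the local-scaling affinity A_ij =
    exp(−‖x_i−x_j‖²/(σ_i σ_j)) with σ_i the distance to the knn-th neighbor.
    A ridge of 1e-9·I is added to the within-class scatter when it is
    (numerically) singular, with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, D = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("LFDA needs at least two classes")
    if n <= d:
        raise ValueError("need more samples than target dimensions")
    dist = cdist(X, X)
    # local-scaling bandwidth: k-th distinct positive neighbor distance, so the
    # affinity is robust to duplicated samples and exact ties
    sigma = np.empty(n)
    for i in range(n):
        vals = np.unique(dist[i])
        vals = vals[vals > 0]
        if vals.size == 0:
            sigma[i] = 1.0
        else:
            sigma[i] = vals[min(knn, vals.size) - 1]
    A = np.exp(-(dist**2) / np.outer(sigma, sigma))

    Ww = np.zeros((n, n))
    Wb = np.full((n, n), 1.0 / n)
    for c in classes:
        idx = np.where(y == c)[0]
        nl = idx.size
        block = np.ix_(idx, idx)
        Ww[block] = A[block] / nl
        Wb[block] = A[block] * (1.0 / n - 1.0 / nl)

    def scatter(W):
        Lw = np.diag(W.sum(axis=1)) - W
        return X.T @ Lw @ X

    Sw, Sb = scatter(Ww), scatter(Wb)
    Sw = 0.5 * (Sw + Sw.T)
    Sb = 0.5 * (Sb + Sb.T)
    ew = np.linalg.eigvalsh(Sw)
    if ew.min() <= 1e-12 * max(ew.max(), 1.0):
        warnings.warn("singular within-class scatter; adding ridge 1e-9*I")
        Sw = Sw + 1e-9 * np.eye(D)
    vals, vecs = eigh(Sb, Sw)
    order = np.argsort(vals)[::-1][:d]
    L = vecs[:, order].T
    # deterministic sign: largest-magnitude component of each row positive
    for row in L:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return MetricProjection(L=np.ascontiguousarray(L))


# ---------------------------------------------------------------------------
# training loop


@dataclass
class TrainLog:
    objective0: float = 0.0
    best_objective: float = 0.0
    monitored: list[tuple[int, float]] = field(default_factory=list)
    rejected_steps: int = 0


def make_queries(X: np.ndarray, y: np.ndarray) -> list[QueryRelevance]:
    """Leave-one-out queries: each item retrieves the rest, same class = relevant."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    queries = []
    for i in range(X.shape[0]):
        keep = np.ones(X.shape[0], dtype=bool)
        keep[i] = False
        queries.append(QueryRelevance(X[i], X[keep], y[keep] == y[i]))
    return queries


def reml_train(
    X: np.ndarray,
    y: np.ndarray,
    config: REMLConfig = REMLConfig(),
) -> tuple[MetricProjection, TrainLog]:
    """Fit the REML projection by SGD from the LFDA initializer.

    One training item is sampled per iteration as the query against the rest;
    the step size is α_t = α₀/(1 + t/t_max) with the scale-free
    α₀ = alpha_scale·(‖L₀‖_F + 1)/(‖∇J(L₀)‖_F + 1).  The monitored objective
    is evaluated every ``monitor_interval`` iterations and the best iterate is
    returned, so the result never scores worse than the initializer.
    Non-finite steps are rejected with the step scale halved.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("every class needs >= 2 training samples")

    rng = np.random.default_rng(config.seed)
    L = lfda_fit(X, y, config.d, config.lfda_knn).L.copy()
    queries = make_queries(X, y)

    J0 = reml_objective(L, queries, config)
    G0 = np.mean([reml_gradient(L, q, config) for q in queries if q.trainable], axis=0)
    alpha0 = config.alpha_scale * (np.linalg.norm(L) + 1.0) / (
        np.linalg.norm(G0) + 1.0
    )

    log = TrainLog(objective0=J0, best_objective=J0, monitored=[(0, J0)])
    best_L = L.copy()
    scale = 1.0
    n = X.shape[0]
    for t in range(1, config.t_max + 1):
        qi = int(rng.integers(n))
        query = queries[qi]
        if not query.trainable:
            continue
        grad = reml_gradient(L, query, config)
        step = scale * alpha0 / (1.0 + t / config.t_max)
        L_new = L - step * grad
        if not np.all(np.isfinite(L_new)):
            scale *= 0.5
            log.rejected_steps += 1
            if log.rejected_steps > 30:
                raise BrainCBIRError("persistent non-finite REML updates")
            continue
        L = L_new
        if t % config.monitor_interval == 0 or t == config.t_max:
            J = reml_objective(L, queries, config)
            if not np.isfinite(J):
                L = best_L.copy()
                scale *= 0.5
                log.rejected_steps += 1
                if log.rejected_steps > 30:
                    raise BrainCBIRError("persistent non-finite REML objective")
                continue
            log.monitored.append((t, J))
            if J < log.best_objective:
                log.best_objective = J
                best_L = L.copy()
    return MetricProjection(L=best_L), log
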