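"""Retrieval ranking and evaluation: Prec@n, AP, mAP, PR curves, patient folds.

A query ranks the database by ascending squared (Mahalanobis or Euclidean)
distance, ties broken by ascending database index.  AP is the mean of the
precisions at the ranks where a relevant item sits; mAP averages AP over
queries.  Cross-validation folds are drawn at the patient level so slices of
one patient never straddle the train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metric import MetricProjection


@dataclass
class RankingList:
    """Database ordering for one query, with distances and relevance flags."""

    order: np.ndarray  # database indices, ascending distance
    distances: np.ndarray  # sorted ascending
    relevance: np.ndarray  # bool, aligned with ``order``

    @property
    def n_relevant(self) -> int:
        return int(self.relevance.sum())


def rank_database(
    query_x: np.ndarray,
    X_db: np.ndarray,
    relevance: np.ndarray,
    metric: MetricProjection | None = None,
) -> RankingList:
    """Full deterministic ranking; ``metric=None`` means Euclidean distance."""
    X_db = np.atleast_2d(np.asarray(X_db, dtype=float))
    query_x = np.asarray(query_x, dtype=float)
    diff = X_db - query_x
    if metric is not None:
        diff = diff @ metric.L.T
    dist = np.einsum("ij,ij->i", diff, diff)
    order = np.argsort(dist, kind="stable")  # stable → ties by ascending index
    return RankingList(
        order=order,
        distances=dist[order],
        relevance=np.asarray(relevance, dtype=bool)[order],
    )


def precision_recall(ranking: RankingList) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at every cutoff n = 1..N."""
    rel = ranking.relevance.astype(float)
    total = rel.sum()
    if total == 0:
        raise ValueError("no relevant items: recall undefined")
    hits = np.cumsum(rel)
    n = np.arange(1, rel.size + 1)
    return hits / total, hits / n


def prec_at_n(ranking: RankingList, n: int) -> float:
    if n < 1 or n > ranking.relevance.size:
        raise ValueError(f"n={n} outside ranking length {ranking.relevance.size}")
    return float(ranking.relevance[:n].mean())


def average_precision(ranking: RankingList) -> float:
    """Mean of Prec@rank over the ranks holding relevant items."""
    rel = ranking.relevance
    if not rel.any():
        raise ValueError("average precision undefined without relevant items")
    hits = np.cumsum(rel)
    ranks = np.arange(1, rel.size + 1)
    return float((hits[rel] / ranks[rel]).mean())


def mean_average_precision(rankings: list[RankingList]) -> float:
    if not rankings:
        raise ValueError("need at least one query")
    return float(np.mean([average_precision(r) for r in rankings]))


def patient_wise_folds(
    patient_ids, n_folds: int, seed: int = 0
) -> np.ndarray:
    """Fold index per record; all slices of a patient share a fold.

    Patients are shuffled with the seeded generator and dealt into
    ``n_folds`` near-equal groups (sizes differ by at most one patient).
    """
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    if n_folds < 1 or n_folds > patients.size:
        raise ValueError("n_folds must be in [1, number of patients]")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(patients)
    fold_of = {}
    for i, chunk in enumerate(np.array_split(shuffled, n_folds)):
        for p in chunk:
            fold_of[p] = i
    return np.array([fold_of[p] for p in patient_ids])


def interpolated_pr_curve(
    rankings: list[RankingList], grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Macro-averaged PR curve on a fixed recall grid.

    Per query the interpolated precision at recall level r is the maximum
    precision achieved at any recall ≥ r; curves are then averaged pointwise.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 21)
    curves = []
    for ranking in rankings:
        rec, prec = precision_recall(ranking)
        interp = np.array([prec[rec >= g].max() if (rec >= g).any() else 0.0
                           for g in grid])
        curves.append(interp)
    return grid, np.mean(curves, axis=0)


@dataclass
class EvalReport:
    """Aggregated retrieval metrics across folds."""

    map_mean: float
    map_sd: float
    prec_at_n: dict[int, tuple[float, float]]  # n -> (mean, sd) over folds
    fold_map: list[float]
    per_class: dict[str, dict[str, float]]
    pr_grid: list[float]
    pr_precision: list[float]
    fold_of_record: list[int]
    excluded_queries: int
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "map_mean": self.map_mean,
            "map_sd": self.map_sd,
            "prec_at_n": {str(k): list(v) for k, v in self.prec_at_n.items()},
            "fold_map": self.fold_map,
            "per_class": self.per_class,
            "pr_grid": self.pr_grid,
            "pr_precision": self.pr_precision,
            "fold_of_record": self.fold_of_record,
            "excluded_queries": self.excluded_queries,
            "config": self.config_echo,
        }
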