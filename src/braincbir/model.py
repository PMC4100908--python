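"""End-to-end retrieval model and cross-validated evaluation.

``RunConfig`` collects every pipeline parameter in one flat namespace; the
defaults follow the reference operating point (w=7, V=1000, k=9, soft
assignment, max pooling, d=3, γ=1e-4, η=1, t_max=1000, 5 patient-wise folds).
``RetrievalModel.fit`` runs normalize → dictionary → partition → features →
metric on training records only; test images only ever query a fitted model,
so no stage can see test-fold data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import bovw, partition as pt
from .errors import ConfigurationError
from .evaluation import (
    EvalReport,
    RankingList,
    average_precision,
    interpolated_pr_curve,
    patient_wise_folds,
    prec_at_n,
    rank_database,
)
from .metric import MetricProjection, REMLConfig, reml_train
from .phantoms import ImageRecord
from .preprocess import NormalizationParams, normalize_intensity


@dataclass(frozen=True)
class RunConfig:
    # BoVW
    w: int = 7
    V: int = 1000
    stride: int = 1
    coding: str = "soft"  # "soft" | "hard"
    K: int = 5
    sigma: float | None = None  # None → median nearest-neighbor word distance
    p: str = "inf"  # pooling order: "inf" | 1
    dict_patch_cap: int = 20000
    kmeans_max_iter: int = 100
    # partition
    partition_kind: str = "learned"  # "learned" | "pyramid" | "whole"
    k: int = 9
    pyramid_levels: int = 3
    lam: float | None = None
    eps: float = 1e-10
    min_leaf_area: float = 0.02
    partition_t_max: int = 1000
    # metric
    metric: str = "reml"  # "reml" | "euclidean"
    d: int = 3
    gamma: float = 1e-4
    eta: float = 1.0
    metric_t_max: int = 1000
    monitor_interval: int = 50
    # normalization
    q_low: float = 0.01
    q_high: float = 0.99
    # evaluation
    n_folds: int = 5
    prec_ns: tuple[int, ...] = (5, 10)
    seed: int = 17

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prec_ns"] = list(d["prec_ns"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "prec_ns" in data:
            data = dict(data, prec_ns=tuple(data["prec_ns"]))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def partition_config(self, k: int | None = None) -> pt.PartitionConfig:
        return pt.PartitionConfig(
            k=self.k if k is None else k,
            lam=self.lam,
            eps=self.eps,
            min_leaf_area=self.min_leaf_area,
            t_max=self.partition_t_max,
        )

    def reml_config(self, seed: int | None = None) -> REMLConfig:
        return REMLConfig(
            gamma=self.gamma,
            eta=self.eta,
            t_max=self.metric_t_max,
            d=self.d,
            seed=self.seed if seed is None else seed,
            monitor_interval=self.monitor_interval,
        )


@dataclass
class RetrievalModel:
    """A fitted retrieval index: dictionary, partition, features, metric."""

    config: RunConfig
    dictionary: bovw.Dictionary = None
    sigma: float = None
    partition: "pt.PartitionTree | pt.SpatialPyramid" = None
    projection: MetricProjection | None = None
    features: np.ndarray = None
    labels: np.ndarray = None
    patient_ids: np.ndarray = None

    # -- fitting ----------------------------------------------------------

    def _normalize(self, record: ImageRecord) -> np.ndarray:
        params = NormalizationParams(self.config.q_low, self.config.q_high)
        return normalize_intensity(record.image, params=params)

    def _encode(self, record: ImageRecord) -> bovw.EncodedROI:
        return bovw.encode_roi(
            self._normalize(record),
            record.roi,
            self.dictionary,
            stride=self.config.stride,
            sigma=self.sigma,
            K=self.config.K,
            coding=self.config.coding,
        )

    def fit(self, records: list[ImageRecord], seed: int | None = None) -> "RetrievalModel":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)

        # dictionary over training-ROI patches (capped subsample for k-means)
        pools = [
            bovw.sample_patches_dense(self._normalize(r), r.roi, cfg.w, cfg.stride)
            for r in records
        ]
        all_desc = np.concatenate([p.descriptors for p in pools])
        if all_desc.shape[0] > cfg.dict_patch_cap:
            idx = rng.choice(all_desc.shape[0], cfg.dict_patch_cap, replace=False)
            all_desc = all_desc[np.sort(idx)]
        self.dictionary = bovw.learn_dictionary(
            all_desc, cfg.V, seed=seed, w=cfg.w, max_iter=cfg.kmeans_max_iter
        )
        self.sigma = cfg.sigma if cfg.sigma is not None else bovw.median_nn_sigma(
            self.dictionary
        )

        encoded = [self._encode(r) for r in records]

        if cfg.partition_kind == "learned":
            self.partition = pt.learn_partition(encoded, cfg.partition_config())
        elif cfg.partition_kind == "pyramid":
            self.partition = pt.spatial_pyramid_partition(cfg.pyramid_levels)
        elif cfg.partition_kind == "whole":
            self.partition = pt.PartitionTree.unit_square()
        else:
            raise ConfigurationError(f"unknown partition_kind {cfg.partition_kind!r}")

        self.features = np.stack(
            [pt.extract_feature(e, self.partition, cfg.p) for e in encoded]
        )
        self.labels = np.array([r.label for r in records])
        self.patient_ids = np.array([r.patient_id for r in records])

        if cfg.metric == "reml":
            self.projection, self.train_log = reml_train(
                self.features, self.labels, cfg.reml_config(seed)
            )
        elif cfg.metric == "euclidean":
            self.projection = None
        else:
            raise ConfigurationError(f"unknown metric {cfg.metric!r}")
        return self

    # -- querying ---------------------------------------------------------

    def feature_of(self, record: ImageRecord) -> np.ndarray:
        return pt.extract_feature(self._encode(record), self.partition, self.config.p)

    def query(self, record: ImageRecord,
              metric: str | None = None) -> RankingList:
        """Rank the fitted (training) database against one query record."""
        proj = self.projection if (metric or self.config.metric) == "reml" else None
        return rank_database(
            self.feature_of(record),
            self.features,
            self.labels == record.label,
            metric=proj,
        )


def evaluate_cv(
    records: list[ImageRecord],
    config: RunConfig,
    seed: int | None = None,
) -> EvalReport:
    """Patient-wise k-fold cross-validated retrieval evaluation.

    Per fold all fitting (dictionary, partition, metric) uses the training
    split only; every test image queries the training database.  Queries
    without any relevant item in the pool are excluded and counted.
    """
    seed = config.seed if seed is None else seed
    patient_ids = [r.patient_id for r in records]
    folds = patient_wise_folds(patient_ids, config.n_folds, seed)
    labels = np.array([r.label for r in records])

    fold_map: list[float] = []
    fold_prec: dict[int, list[float]] = {n: [] for n in config.prec_ns}
    per_class_aps: dict[str, list[float]] = {c: [] for c in np.unique(labels)}
    all_rankings: list[RankingList] = []
    excluded = 0
    for f in range(config.n_folds):
        train = [r for r, g in zip(records, folds) if g != f]
        test = [r for r, g in zip(records, folds) if g == f]
        model = RetrievalModel(config).fit(train, seed=seed + f)
        aps, precs = [], {n: [] for n in config.prec_ns}
        for rec in test:
            ranking = model.query(rec)
            if ranking.n_relevant == 0:
                excluded += 1
                continue
            ap = average_precision(ranking)
            aps.append(ap)
            per_class_aps[rec.label].append(ap)
            all_rankings.append(ranking)
            for n in config.prec_ns:
                if n <= ranking.relevance.size:
                    precs[n].append(prec_at_n(ranking, n))
        if aps:
            fold_map.append(float(np.mean(aps)))
            for n in config.prec_ns:
                if precs[n]:
                    fold_prec[n].append(float(np.mean(precs[n])))

    grid, prec_curve = interpolated_pr_curve(all_rankings)
    return EvalReport(
        map_mean=float(np.mean(fold_map)),
        map_sd=float(np.std(fold_map)),
        prec_at_n={
            n: (float(np.mean(v)), float(np.std(v))) for n, v in fold_prec.items() if v
        },
        fold_map=fold_map,
        per_class={
            c: {"map": float(np.mean(v)), "n_queries": len(v)}
            for c, v in per_class_aps.items()
            if v
        },
        pr_grid=grid.tolist(),
        pr_precision=prec_curve.tolist(),
        fold_of_record=folds.tolist(),
        excluded_queries=excluded,
        config_echo=config.to_dict(),
    )
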