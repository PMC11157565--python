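"""Two-stage pipeline orchestration and regression metrics.

Stage 1 ranks features (mRMR by default) and picks the candidate subset by
sequential forward search under k-fold PLS cross-validation; Stage 2 runs
the multi-objective swarm over the candidate set and returns the Pareto
front, re-expressed in original column indices, with per-member regression
metrics computed from out-of-fold predictions on the same fold assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cmopso import CmopsoResult, run_cmopso
from .io import FeatureTable, RunConfig
from .pareto import Archive, ArchiveEntry, archive_update
from .relevance import MrmrRanking, correlation_rank, mrmr_rank
from .wrapper import (CandidateSubset, CvConfig, kfold_pls_predictions,
                      kfold_pls_rmse, sfs_candidate_selection)

logger = logging.getLogger("swarmselect")

__all__ = [
    "RegressionMetrics",
    "McmopsoResult",
    "compute_metrics",
    "run_mcmopso",
    "run_repeated",
]


@dataclass
class RegressionMetrics:
    rmse: float
    r2: float
    mae: float

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.mae < 0:
            raise ValueError("rmse and mae must be nonnegative")
        if self.mae > self.rmse + 1e-12:
            raise ValueError("mae cannot exceed rmse")


@dataclass
class McmopsoResult:
    """Everything a two-stage run produced, in original column space."""

    ranking: MrmrRanking
    candidate: CandidateSubset
    front: list[ArchiveEntry]
    metrics_per_front_member: list[RegressionMetrics]
    config_echo: RunConfig
    all_feature_names: list[str]
    history: list[tuple[int, float]] = field(default_factory=list)

    def feature_names(self, entry: ArchiveEntry) -> list[str]:
        return [self.all_feature_names[i]
                for i in sorted(entry.feature_indices)]

    def min_rmse_entry(self) -> ArchiveEntry:
        return min(self.front, key=lambda e: e.objectives[1])


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionMetrics:
    """RMSE, R^2 and MAE of a prediction vector."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y_true is constant")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return RegressionMetrics(rmse=rmse, r2=r2, mae=mae)


def _rank(X, y: np.ndarray, config: RunConfig) -> MrmrRanking:
    if config.filter_method == "mrmr":
        return mrmr_rank(X, y, n_bins=config.n_bins,
                         relevance_only=config.relevance_only)
    return correlation_rank(X, y, method=config.filter_method)


def run_mcmopso(X, y: np.ndarray, config: RunConfig) -> McmopsoResult:
    """Execute ranking, forward search and the swarm under one seed lineage.

    All randomness (fold shuffle, swarm initialization and dynamics) derives
    from ``config.seed`` through spawned child generators, so identical
    config implies an identical result.
    """
    if isinstance(X, FeatureTable):
        names = X.feature_names
        V = X.values
    else:
        V = np.asarray(X, float)
        names = [f"f{j}" for j in range(V.shape[1])]
    y = np.asarray(y, float).ravel()
    if len(y) != V.shape[0]:
        raise ValueError("target length does not match sample count")

    ss = np.random.SeedSequence(config.seed)
    shuffle_seed, swarm_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                for s in ss.spawn(2))
    cv = CvConfig(folds=config.cv_folds, pls_components=config.pls_components,
                  shuffle_seed=shuffle_seed, pooled=config.pooled_rmse)

    ranking = _rank(V, y, config)
    step = config.resolve_step(V.shape[1])
    candidate = sfs_candidate_selection(ranking, V, y, step, cv)
    can_idx = candidate.feature_indices
    X_can = V[:, can_idx]

    if len(can_idx) == 1:
        logger.warning("candidate set has a single feature; "
                       "skipping the swarm stage")
        entry = ArchiveEntry((1, candidate.rmse), frozenset([0]),
                             np.ones(1))
        opt = CmopsoResult(front=[entry], history=[])
    else:
        opt = run_cmopso(X_can, y, config,
                         rng=np.random.default_rng(swarm_seed), cv=cv)

    # map archive entries back to original column indices
    front: list[ArchiveEntry] = []
    metrics: list[RegressionMetrics] = []
    for e in sorted(opt.front, key=lambda e: e.objectives):
        local = np.asarray(sorted(e.feature_indices), dtype=int)
        original = frozenset(int(i) for i in can_idx[local])
        front.append(ArchiveEntry(e.objectives, original, e.position))
        pred = kfold_pls_predictions(V[:, can_idx[local]], y, cv)
        metrics.append(compute_metrics(y, pred))

    return McmopsoResult(ranking=ranking, candidate=candidate, front=front,
                         metrics_per_front_member=metrics,
                         config_echo=config, all_feature_names=names,
                         history=opt.history)


def run_repeated(X, y: np.ndarray, config: RunConfig,
                 repeats: int = 10) -> dict[int, tuple[float, float]]:
    """Benchmark-style aggregation over independent seeded runs.

    Each run keeps, for every subset size f1 on its front, the minimum f2;
    sizes seen in every run are then summarized as (mean, sd) across runs.
    Returns {f1: (mean_rmse, sd_rmse)} for sizes present in all repeats.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    per_run: list[dict[int, float]] = []
    for r in range(repeats):
        cfg = RunConfig(**{**config.to_dict(), "seed": config.seed + r})
        res = run_mcmopso(X, y, cfg)
        best: dict[int, float] = {}
        for e in res.front:
            f1, f2 = e.objectives
            if f1 not in best or f2 < best[f1]:
                best[f1] = f2
        per_run.append(best)
    common = set(per_run[0])
    for b in per_run[1:]:
        common &= set(b)
    out: dict[int, tuple[float, float]] = {}
    for f1 in sorted(common):
        vals = np.array([b[f1] for b in per_run])
        out[f1] = (float(vals.mean()), float(vals.std(ddof=1 if repeats > 1
                                                      else 0)))
    return out
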