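"""Stage-1 wrapper: PLS cross-validation and sequential forward search.

Ranked feature prefixes are scored by k-fold cross-validated PLS regression
RMSE; the prefix with the smallest CV RMSE becomes the candidate subset
handed to the Stage-2 optimizer.  Rows are shuffled once per run, so a
subset's RMSE is a deterministic function of the subset — the optimizer
compares subsets on a fixed fold assignment.

The PLS engine is a single-target NIPALS implementation following the usual
centering/scaling conventions (train-fold mean and ddof-1 standard
deviation, zero deviations treated as 1), numerically identical to
scikit-learn's ``PLSRegression`` while being cheap enough for the tens of
thousands of fold fits a swarm run performs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable
from .relevance import MrmrRanking

logger = logging.getLogger("swarmselect")

# (requested, cap) pairs already warned about, to keep swarm-stage logs sane
_warned_caps: set[tuple[int, int]] = set()

__all__ = [
    "CvConfig",
    "CandidateSubset",
    "pls1_fit",
    "kfold_pls_rmse",
    "sfs_candidate_selection",
]


@dataclass
class CvConfig:
    """Cross-validation settings shared by both stages."""

    folds: int = 10
    pls_components: int = 2
    shuffle_seed: int = 0
    pooled: bool = False  # pooled-residual RMSE instead of mean of fold RMSEs

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.pls_components < 1:
            raise ValueError("need at least 1 PLS component")


@dataclass
class CandidateSubset:
    """Stage-1 output: the chosen prefix and the full evaluation trace."""

    feature_indices: np.ndarray
    rmse: float
    trace: list[tuple[int, float]]

    def __post_init__(self) -> None:
        self.feature_indices = np.asarray(self.feature_indices, dtype=int)
        if len(set(self.feature_indices.tolist())) != len(self.feature_indices):
            raise ValueError("candidate indices must be unique")


def pls1_fit(X: np.ndarray, y: np.ndarray, n_components: int):
    """Fit single-target PLS (NIPALS); returns a predict(X_new) closure."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    xm = X.mean(axis=0)
    xs = X.std(axis=0, ddof=1)
    xs[xs == 0] = 1.0
    ym = y.mean()
    ys = y.std(ddof=1) or 1.0
    Xc = (X - xm) / xs
    yc = (y - ym) / ys

    k = min(n_components, p, n - 1)
    W = np.empty((p, k))
    P = np.empty((p, k))
    q = np.empty(k)
    used = 0
    for a in range(k):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:  # residual exhausted
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        P[:, a] = (Xc.T @ t) / tt
        q[a] = (yc @ t) / tt
        Xc = Xc - np.outer(t, P[:, a])
        yc = yc - q[a] * t
        W[:, a] = w
        used += 1
    if used:
        coef = W[:, :used] @ np.linalg.solve(P[:, :used].T @ W[:, :used],
                                             q[:used])
    else:
        coef = np.zeros(p)

    def predict(X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, float)
        return ((X_new - xm) / xs) @ coef * ys + ym

    return predict


def fold_indices(n: int, folds: int, shuffle_seed: int) -> list[np.ndarray]:
    """One shuffle, then contiguous splits — fixed for a whole run."""
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")
    rng = np.random.default_rng(shuffle_seed)
    perm = rng.permutation(n)
    return np.array_split(perm, folds)


def kfold_pls_rmse(X_sub: np.ndarray, y: np.ndarray, cv: CvConfig) -> float:
    """Mean over folds of held-out RMSE for PLS on the given submatrix.

    The component count is capped at the usable rank of each training fold
    (min of its row count minus one and the subset size), with a warning
    when the cap bites.
    """
    X_sub = np.asarray(X_sub, float)
    if X_sub.ndim == 1:
        X_sub = X_sub[:, None]
    y = np.asarray(y, float).ravel()
    n, p = X_sub.shape
    if p == 0:
        raise ValueError("empty feature subset")
    splits = fold_indices(n, cv.folds, cv.shuffle_seed)
    all_idx = np.arange(n)
    fold_rmses = []
    sq_residuals = []
    for test_idx in splits:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        cap = min(len(train_idx) - 1, p)
        if cv.pls_components > cap:
            key = (cv.pls_components, cap)
            if key not in _warned_caps:
                _warned_caps.add(key)
                logger.warning("pls_components reduced from %d to usable "
                               "rank %d", cv.pls_components, cap)
        predict = pls1_fit(X_sub[train_idx], y[train_idx],
                           min(cv.pls_components, cap))
        resid = y[test_idx] - predict(X_sub[test_idx])
        fold_rmses.append(float(np.sqrt(np.mean(resid ** 2))))
        sq_residuals.append(resid ** 2)
    if cv.pooled:
        return float(np.sqrt(np.mean(np.concatenate(sq_residuals))))
    return float(np.mean(fold_rmses))


def kfold_pls_predictions(X_sub: np.ndarray, y: np.ndarray,
                          cv: CvConfig) -> np.ndarray:
    """Out-of-fold predictions for every sample, same folds as the RMSE."""
    X_sub = np.asarray(X_sub, float)
    if X_sub.ndim == 1:
        X_sub = X_sub[:, None]
    y = np.asarray(y, float).ravel()
    n, p = X_sub.shape
    pred = np.empty(n)
    for test_idx in fold_indices(n, cv.folds, cv.shuffle_seed):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        cap = min(int(train_mask.sum()) - 1, p)
        fit = pls1_fit(X_sub[train_mask], y[train_mask],
                       min(cv.pls_components, cap))
        pred[test_idx] = fit(X_sub[test_idx])
    return pred


def sfs_candidate_selection(
    ranking: MrmrRanking,
    X,
    y: np.ndarray,
    step: int,
    cv: CvConfig,
) -> CandidateSubset:
    """Evaluate growing prefixes of a ranking; keep the RMSE-minimizing one.

    Prefix sizes are step, 2*step, ... up to m (a final partial prefix is
    included).  Ties break toward the smaller prefix.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    order = ranking.order
    m = len(order)
    if m == 0:
        raise ValueError("empty ranking")
    V = X.values if isinstance(X, FeatureTable) else np.asarray(X, float)
    sizes = list(range(step, m + 1, step))
    if not sizes or sizes[-1] != m:
        sizes.append(m)
    trace: list[tuple[int, float]] = []
    best_size, best_rmse = None, np.inf
    for size in sizes:
        rmse = kfold_pls_rmse(V[:, order[:size]], y, cv)
        trace.append((size, rmse))
        if rmse < best_rmse:
            best_size, best_rmse = size, rmse
    return CandidateSubset(order[:best_size].copy(), best_rmse, trace)
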