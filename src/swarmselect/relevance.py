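"""Mutual-information estimation and Stage-1 feature ranking.

Mutual information I(x;y) = E[ln p(x,y) / (p(x)p(y))] is estimated by the
histogram plug-in: continuous variables are discretized into equal-width
bins sized by a joint-occupancy rule (see :func:`discretize`), natively
discrete ones (integer-coded, <= 20 levels) are used as-is, and the sum
runs over nonzero joint cells, in nats.  The mRMR
ranking is the classical greedy incremental scheme: the first feature
maximizes relevance I(f, y); each later pick maximizes

    I(f, y) - (1/|S|) * sum_{s in S} I(f, s)

over features not yet selected, trading relevance against mean redundancy
with the already-selected set S.  Pearson/Spearman |correlation| rankings
are provided as filter baselines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import FeatureTable

logger = logging.getLogger("swarmselect")

__all__ = [
    "DiscretizedVariable",
    "MrmrRanking",
    "discretize",
    "estimate_mi",
    "mrmr_rank",
    "correlation_rank",
]

#: natively discrete input (all-integer values) with at most this many
#: distinct levels is used as-is instead of being binned
MAX_NATIVE_LEVELS = 20


@dataclass
class DiscretizedVariable:
    """Integer codes of a variable plus the binning that produced them."""

    codes: np.ndarray
    n_levels: int
    bin_edges: np.ndarray  # empty for natively discrete input

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if len(self.codes) and (self.codes.min() < 0
                                or self.codes.max() >= self.n_levels):
            raise ValueError("codes out of range [0, n_levels)")


@dataclass
class MrmrRanking:
    """A full feature ordering with per-step criterion values.

    ``order[k]`` is the original column index picked at step k; ``scores[k]``
    the criterion value (relevance minus mean redundancy) it achieved there;
    ``relevance[i]`` the plain I(f_i, y) of column i.
    """

    order: np.ndarray
    scores: np.ndarray
    relevance: np.ndarray
    method: str = "mrmr"

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if sorted(self.order.tolist()) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of feature indices")
        if len(self.scores) != len(self.order):
            raise ValueError("scores must align with order")


def discretize(x: np.ndarray, n_bins: int | None = None) -> DiscretizedVariable:
    """Map a numeric vector to integer codes for plug-in estimation.

    Integer-coded input with <= 20 distinct values keeps its own levels;
    anything else gets equal-width bins.  The automatic bin count keeps the
    expected occupancy of each joint cell at about five observations,
    k = ceil(sqrt(n / 5)) (never below 2): a pairwise estimate over k x k
    cells then rests on n >= ~5k^2 samples, which controls the variance of
    the plug-in at the small n this tool targets (k grows like n^(1/2)
    per *joint* axis rather than per marginal).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    uniq = np.unique(x)
    if len(uniq) == 1:
        return DiscretizedVariable(np.zeros(n, dtype=np.intp), 1,
                                   np.empty(0))
    if (n_bins is None and len(uniq) <= MAX_NATIVE_LEVELS
            and np.all(uniq == np.floor(uniq))):
        codes = np.searchsorted(uniq, x)
        return DiscretizedVariable(codes.astype(np.intp), len(uniq),
                                   np.empty(0))
    k = n_bins if n_bins is not None else max(2, math.ceil(math.sqrt(n / 5)))
    edges = np.linspace(x.min(), x.max(), k + 1)
    codes = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, k - 1)
    return DiscretizedVariable(codes.astype(np.intp), k, edges)


def _mi_from_codes(a: DiscretizedVariable, b: DiscretizedVariable) -> float:
    """Plug-in MI (nats) between two coded variables."""
    n = len(a.codes)
    joint = np.bincount(a.codes * b.n_levels + b.codes,
                        minlength=a.n_levels * b.n_levels).astype(float)
    joint = joint.reshape(a.n_levels, b.n_levels) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz]
                                         / np.outer(pa, pb)[nz])))
    return max(mi, 0.0)  # guard tiny negative round-off


def estimate_mi(x: np.ndarray, y: np.ndarray,
                n_bins: int | None = None) -> float:
    """Histogram plug-in mutual information between two vectors, in nats.

    A constant vector has zero entropy, hence MI 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return _mi_from_codes(discretize(x, n_bins), discretize(y, n_bins))


def _as_matrix(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureTable) else np.asarray(X, float)


def mrmr_rank(
    X,
    y: np.ndarray,
    max_rank: int | None = None,
    n_bins: int | None = None,
    relevance_only: bool = False,
) -> MrmrRanking:
    """Greedy max-relevance min-redundancy feature ranking.

    Parameters
    ----------
    X : FeatureTable or (n, m) array
    y : target column, must be nonconstant
    max_rank : stop after this many positions (the remainder of ``order`` is
        filled with the unselected indices in ascending order and their
        scores are NaN)
    relevance_only : rank once by I(f, y) alone, skipping the redundancy
        charge (one-shot scoring mode)

    Ties in every argmax break toward the lower original column index.
    """
    V = _as_matrix(X)
    n, m = V.shape
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    disc = [discretize(V[:, j], n_bins) for j in range(m)]
    dy = discretize(y, n_bins)
    relevance = np.array([_mi_from_codes(d, dy) for d in disc])
    if all(d.n_levels == 1 for d in disc):
        raise ValueError("no informative features: all features constant")

    if relevance_only:
        order = np.lexsort((np.arange(m), -relevance))
        return MrmrRanking(order, relevance[order].copy(), relevance,
                           method="mrmr-relevance-only")

    k = m if max_rank is None else min(max_rank, m)
    order = np.empty(m, dtype=int)
    scores = np.full(m, np.nan)
    selected = np.zeros(m, dtype=bool)
    red_sum = np.zeros(m)  # sum of MI(f, s) over selected s
    for step in range(k):
        crit = relevance - (red_sum / step if step else 0.0)
        crit = np.where(selected, -np.inf, crit)
        pick = int(np.argmax(crit))  # argmax takes the first (lowest index)
        order[step] = pick
        scores[step] = crit[pick]
        selected[pick] = True
        if step + 1 < k:
            dp = disc[pick]
            for j in np.flatnonzero(~selected):
                red_sum[j] += _mi_from_codes(disc[j], dp)
    if k < m:
        order[k:] = np.flatnonzero(~selected)
    return MrmrRanking(order, scores, relevance)


def correlation_rank(X, y: np.ndarray, method: str = "pearson") -> MrmrRanking:
    """Filter baseline: rank features by |Pearson| or |Spearman| with y.

    Constant features get correlation 0 (ranked last) with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    V = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    m = V.shape[1]
    corr = np.zeros(m)
    n_const = 0
    if method == "spearman":
        yv = stats.rankdata(y)
    else:
        yv = y
    for j in range(m):
        col = V[:, j]
        if np.ptp(col) == 0:
            n_const += 1
            continue
        xv = stats.rankdata(col) if method == "spearman" else col
        corr[j] = abs(np.corrcoef(xv, yv)[0, 1])
    if n_const:
        logger.warning("%d constant feature(s) assigned correlation 0",
                       n_const)
    order = np.lexsort((np.arange(m), -corr))
    return MrmrRanking(order, corr[order].copy(), corr, method=method)
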