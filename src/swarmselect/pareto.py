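"""Objective-space machinery for the multi-objective optimizer.

Both objectives are minimized: f1 = number of selected features, f2 = the
subset's cross-validated RMSE.  The non-dominated set is held in a bounded
external archive truncated by crowding distance (NSGA-II convention:
per-objective gaps normalized by the objective's range, extremes infinite),
and leaders are drawn by adaptive-grid roulette — the objective space is
partitioned into a Mesh x Mesh grid over the archive's bounding box and a
cell is picked with probability inversely proportional to its occupancy,
favouring sparse regions of the front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArchiveEntry",
    "Archive",
    "GridConfig",
    "dominates",
    "non_dominated_filter",
    "crowding_distance",
    "archive_update",
    "select_leader",
]


@dataclass
class ArchiveEntry:
    """One non-dominated solution: objectives, subset, and its encoding."""

    objectives: tuple
    feature_indices: frozenset
    position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.objectives = (int(self.objectives[0]), float(self.objectives[1]))
        self.feature_indices = frozenset(int(i) for i in self.feature_indices)
        if len(self.feature_indices) != self.objectives[0]:
            raise ValueError("f1 must equal the subset size")


@dataclass
class Archive:
    """Bounded store of pairwise non-dominated entries."""

    capacity: int
    entries: list[ArchiveEntry] = field(default_factory=list)
    crowding: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("archive capacity must be >= 1")

    def objective_matrix(self) -> np.ndarray:
        return np.array([e.objectives for e in self.entries], dtype=float)


@dataclass
class GridConfig:
    """Adaptive-grid settings: divisions per objective plus bound padding."""

    divisions: int = 20
    inflation: float = 0.1

    def __post_init__(self) -> None:
        if self.divisions < 1:
            raise ValueError("divisions must be >= 1")


def dominates(a, b) -> bool:
    """Pareto dominance (minimization): a no worse everywhere, better once."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_filter(points) -> np.ndarray:
    """Indices of points dominated by no other point; duplicates retained."""
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n = len(P)
    if n == 0:
        return np.empty(0, dtype=int)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        # any j that is <= everywhere and < somewhere dominates i
        le = np.all(P <= P[i], axis=1)
        lt = np.any(P < P[i], axis=1)
        if np.any(le & lt):
            keep[i] = False
    return np.flatnonzero(keep)


def crowding_distance(front) -> np.ndarray:
    """Per-solution spread measure over a front of objective vectors.

    Fronts of one or two points are all-infinite (boundary convention); an
    objective with zero range contributes nothing.  Neighbors are taken
    over *distinct* objective values, so tied points share one distance and
    every point attaining a per-objective extreme is infinite — this keeps
    the measure permutation-equivariant, which a stable-sort formulation
    is not under ties.
    """
    F = np.asarray(front, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    n = len(F)
    if n == 0:
        raise ValueError("empty front")
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for k in range(F.shape[1]):
        v = F[:, k]
        rng = v.max() - v.min()
        if rng == 0:
            continue
        uniq = np.unique(v)  # sorted distinct values
        pos = np.searchsorted(uniq, v)
        extreme = (pos == 0) | (pos == len(uniq) - 1)
        interior = ~extreme
        dist[interior] += (uniq[pos[interior] + 1]
                           - uniq[pos[interior] - 1]) / rng
        dist[extreme] = np.inf
    return dist


def archive_update(archive: Archive, candidates) -> Archive:
    """Fold candidates into the archive, keeping it non-dominated and bounded.

    Exact duplicates (same objectives AND same feature set) collapse to the
    earlier-inserted copy; equal objective vectors with different subsets
    are distinct solutions and both stay.  Over capacity, the entry with
    the smallest crowding distance is removed one at a time, recomputing
    distances after each removal; crowding ties drop the later-inserted
    entry.
    """
    combined: list[ArchiveEntry] = []
    seen: set[tuple] = set()
    for e in list(archive.entries) + list(candidates):
        key = (e.objectives, e.feature_indices)
        if key in seen:
            continue
        seen.add(key)
        combined.append(e)
    if not combined:
        return Archive(capacity=archive.capacity)
    objs = np.array([e.objectives for e in combined], dtype=float)
    keep = non_dominated_filter(objs)
    entries = [combined[i] for i in keep]
    while len(entries) > archive.capacity:
        cd = crowding_distance([e.objectives for e in entries])
        worst = int(np.flatnonzero(cd == cd.min())[-1])  # later-inserted
        del entries[worst]
    cd = crowding_distance([e.objectives for e in entries])
    return Archive(capacity=archive.capacity, entries=entries, crowding=cd)


def select_leader(archive: Archive, grid: GridConfig,
                  rng: np.random.Generator) -> ArchiveEntry:
    """Draw a leader by inverse-occupancy roulette over grid cells."""
    if not archive.entries:
        raise ValueError("cannot select a leader from an empty archive")
    if len(archive.entries) == 1:
        return archive.entries[0]
    F = archive.objective_matrix()
    lo = F.min(axis=0)
    hi = F.max(axis=0)
    span = hi - lo
    pad = grid.inflation * np.where(span > 0, span, 1.0) / 2.0
    lo = lo - pad
    width = (span + 2 * pad) / grid.divisions
    cells = np.floor((F - lo) / width).astype(int)
    cells = np.clip(cells, 0, grid.divisions - 1)
    keys = cells[:, 0] * grid.divisions + cells[:, 1]
    uniq, inverse, counts = np.unique(keys, return_inverse=True,
                                      return_counts=True)
    weights = 1.0 / counts
    probs = weights / weights.sum()
    cell = rng.choice(len(uniq), p=probs)
    members = np.flatnonzero(inverse == cell)
    return archive.entries[int(rng.choice(members))]
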