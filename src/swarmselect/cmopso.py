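"""CMOPSO: multi-objective PSO with scheduled coefficients.

The optimizer searches subsets of the Stage-1 candidate features,
minimizing (f1, f2) = (subset size, cross-validated PLS RMSE).  Particles
live in [0, 1]^D, one dimension per candidate feature, and decode to the
subset of dimensions whose position exceeds a threshold (default 0.6).
Velocity and position follow the classical update

    v' = w*v + c1*r1*(pbest - x) + c2*r2*(leader - x),   x' = x + v',

with a leader re-drawn per particle from the Pareto archive by grid
roulette.  What distinguishes CMOPSO from plain MOPSO is its coefficient
schedules: inertia decreases nonlinearly,

    w(t) = (w_max - w_min)*(t/T - 1)^2 + w_min,

and the acceleration factors ramp linearly — the cognitive factor c1 from
2.75 down to 1.25 and the social factor c2 from 0.5 up to 2.25 — so early
iterations favour independent exploration and late ones convergence toward
the archive.  The ``literal_c2`` flag reproduces the alternative c2 ramp
``c2f + (c2f - c2i)*(t/T)``, which decreases below zero and is kept only
for comparison.  Plain MOPSO runs the identical loop with constant w and
c1 = c2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import RunConfig
from .pareto import (Archive, ArchiveEntry, GridConfig, archive_update,
                     dominates, select_leader)
from .wrapper import CvConfig, kfold_pls_rmse

logger = logging.getLogger("swarmselect")

__all__ = [
    "ScheduleConfig",
    "Particle",
    "CmopsoResult",
    "inertia_weight",
    "acceleration_factors",
    "update_velocity",
    "update_position",
    "decode_particle",
    "evaluate_particle",
    "update_pbest",
    "run_cmopso",
]

#: velocity clamp: half the [0, 1] position range
V_MAX = 0.5


@dataclass
class ScheduleConfig:
    """Coefficient schedules over T iterations (defaults per CMOPSO)."""

    T: int
    w_max: float = 0.9
    w_min: float = 0.4
    c1i: float = 1.25
    c1f: float = 2.75
    c2i: float = 2.25
    c2f: float = 0.5
    literal_c2: bool = False

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (self.w_max > self.w_min):
            raise ValueError("w_max must exceed w_min")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_objectives: tuple
    pbest_subset: frozenset


@dataclass
class CmopsoResult:
    front: list[ArchiveEntry]
    history: list[tuple[int, float]]  # (archive size, best f2) per iteration
    n_evaluations: int = 0


def inertia_weight(t: int, sched: ScheduleConfig) -> float:
    """Nonlinearly decreasing inertia: w_max at t=0 down to w_min at t=T."""
    if not 0 <= t <= sched.T:
        raise ValueError(f"iteration {t} outside [0, {sched.T}]")
    return (sched.w_max - sched.w_min) * (t / sched.T - 1.0) ** 2 + sched.w_min


def acceleration_factors(t: int, sched: ScheduleConfig) -> tuple[float, float]:
    """Linear ramps: c1 from c1f down to c1i, c2 from c2f up to c2i."""
    if not 0 <= t <= sched.T:
        raise ValueError(f"iteration {t} outside [0, {sched.T}]")
    frac = t / sched.T
    c1 = sched.c1f + (sched.c1i - sched.c1f) * frac
    if sched.literal_c2:
        c2 = sched.c2f + (sched.c2f - sched.c2i) * frac
    else:
        c2 = sched.c2f + (sched.c2i - sched.c2f) * frac
    return c1, c2


def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest_position: np.ndarray,
    leader_position: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    v_max: float = V_MAX,
) -> np.ndarray:
    """One velocity update with fresh per-dimension r1, r2 ~ U(0, 1)."""
    D = len(velocity)
    r1 = rng.random(D)
    r2 = rng.random(D)
    v = (w * velocity
         + c1 * r1 * (pbest_position - position)
         + c2 * r2 * (leader_position - position))
    return np.clip(v, -v_max, v_max)


def update_position(position: np.ndarray,
                    velocity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Add velocity, clip to [0, 1]; clipped dimensions lose their velocity."""
    x = position + velocity
    clipped = (x < 0.0) | (x > 1.0)
    x = np.clip(x, 0.0, 1.0)
    v = np.where(clipped, 0.0, velocity)
    return x, v


def decode_particle(position: np.ndarray, threshold: float) -> np.ndarray:
    """Indices above the threshold; an empty decode repairs to {argmax}."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    idx = np.flatnonzero(position > threshold)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(position))])
    return idx


def evaluate_particle(subset, X_can: np.ndarray, y: np.ndarray,
                      cv: CvConfig, cache: dict | None = None) -> tuple:
    """(f1, f2) for a subset of candidate columns; memoized per run."""
    idx = np.asarray(sorted(int(i) for i in subset), dtype=int)
    if len(idx) == 0:
        raise ValueError("cannot evaluate an empty subset")
    key = tuple(idx.tolist())
    if cache is not None and key in cache:
        return cache[key]
    f2 = kfold_pls_rmse(X_can[:, idx], y, cv)
    obj = (len(idx), f2)
    if cache is not None:
        cache[key] = obj
    return obj


def update_pbest(particle: Particle, objectives: tuple, subset,
                 rng: np.random.Generator) -> None:
    """Dominance-based personal-best update; coin flip when incomparable."""
    new_wins = dominates(objectives, particle.pbest_objectives)
    old_wins = dominates(particle.pbest_objectives, objectives)
    if new_wins or (not old_wins and rng.random() < 0.5):
        particle.pbest_position = particle.position.copy()
        particle.pbest_objectives = tuple(objectives)
        particle.pbest_subset = frozenset(int(i) for i in subset)


def run_cmopso(
    X_can: np.ndarray,
    y: np.ndarray,
    config: RunConfig,
    rng: np.random.Generator | None = None,
    cv: CvConfig | None = None,
) -> CmopsoResult:
    """Full optimizer loop over subsets of the candidate features.

    Positions initialize uniformly on [0, 1]^D with zero velocities; the
    initial evaluations seed the archive; each of the T iterations draws
    schedules, moves every particle toward its pbest and a grid-roulette
    leader, re-evaluates, updates pbests and folds the new points into the
    archive.  The final archive is the returned Pareto front.
    """
    X_can = np.asarray(X_can, float)
    if X_can.ndim == 1:
        X_can = X_can[:, None]
    y = np.asarray(y, float).ravel()
    D = X_can.shape[1]
    if D < 1:
        raise ValueError("candidate set is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if cv is None:
        cv = CvConfig(folds=config.cv_folds,
                      pls_components=config.pls_components,
                      shuffle_seed=config.seed, pooled=config.pooled_rmse)
    sched = ScheduleConfig(T=config.iterations, w_max=config.w_max,
                           w_min=config.w_min, c1i=config.c1i,
                           c1f=config.c1f, c2i=config.c2i, c2f=config.c2f,
                           literal_c2=config.literal_c2)
    grid = GridConfig(divisions=config.mesh_divisions)
    cache: dict = {}

    swarm: list[Particle] = []
    seeds: list[ArchiveEntry] = []
    for _ in range(config.pop_size):
        pos = rng.random(D)
        subset = decode_particle(pos, config.decode_threshold)
        obj = evaluate_particle(subset, X_can, y, cv, cache)
        swarm.append(Particle(position=pos, velocity=np.zeros(D),
                              pbest_position=pos.copy(),
                              pbest_objectives=obj,
                              pbest_subset=frozenset(subset.tolist())))
        seeds.append(ArchiveEntry(obj, frozenset(subset.tolist()),
                                  pos.copy()))
    archive = archive_update(Archive(capacity=config.archive_size), seeds)

    history: list[tuple[int, float]] = []
    for t in range(1, config.iterations + 1):
        if config.optimizer == "mopso":
            w, c1, c2 = config.w_max, 2.0, 2.0
        else:
            w = inertia_weight(t, sched)
            c1, c2 = acceleration_factors(t, sched)
        new_entries: list[ArchiveEntry] = []
        for p in swarm:
            leader = select_leader(archive, grid, rng)
            p.velocity = update_velocity(p.velocity, p.position,
                                         p.pbest_position, leader.position,
                                         w, c1, c2, rng)
            p.position, p.velocity = update_position(p.position, p.velocity)
            subset = decode_particle(p.position, config.decode_threshold)
            obj = evaluate_particle(subset, X_can, y, cv, cache)
            update_pbest(p, obj, subset, rng)
            new_entries.append(ArchiveEntry(obj, frozenset(subset.tolist()),
                                            p.position.copy()))
        archive = archive_update(archive, new_entries)
        best_f2 = min(e.objectives[1] for e in archive.entries)
        history.append((len(archive.entries), best_f2))

    return CmopsoResult(front=list(archive.entries), history=history,
                        n_evaluations=len(cache))
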