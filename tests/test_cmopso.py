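import numpy as np
import pytest

from swarmselect import (CvConfig, RunConfig, ScheduleConfig,
                         acceleration_factors, decode_particle,
                         inertia_weight, kfold_pls_rmse, run_cmopso)
from swarmselect.cmopso import (Particle, evaluate_particle, update_pbest,
                                update_position, update_velocity)
from swarmselect.pareto import dominates


class FixedRng:
    """Stub generator returning preset uniforms, for hand-checked updates."""

    def __init__(self, *values):
        self.values = list(values)

    def random(self, size=None):
        v = self.values.pop(0)
        return np.full(size, v) if size is not None else v


@pytest.fixture
def sched():
    return ScheduleConfig(T=300)


class TestSchedules:
    def test_inertia_endpoints_and_midpoint(self, sched):
        assert inertia_weight(0, sched) == pytest.approx(0.9, abs=1e-12)
        assert inertia_weight(300, sched) == pytest.approx(0.4, abs=1e-12)
        assert inertia_weight(150, sched) == pytest.approx(0.525, abs=1e-12)

    def test_inertia_monotone_decreasing_and_bounded(self, sched):
        w = [inertia_weight(t, sched) for t in range(301)]
        assert all(a > b for a, b in zip(w, w[1:]))
        assert min(w) >= 0.4 and max(w) <= 0.9

    def test_acceleration_endpoints(self, sched):
        assert acceleration_factors(0, sched) == pytest.approx((2.75, 0.5))
        assert acceleration_factors(300, sched) == pytest.approx((1.25, 2.25))

    def test_acceleration_midpoint(self, sched):
        c1, c2 = acceleration_factors(150, sched)
        assert (c1, c2) == pytest.approx((2.0, 1.375), abs=1e-12)

    def test_literal_c2_variant_decreases(self):
        s = ScheduleConfig(T=100, literal_c2=True)
        assert acceleration_factors(100, s)[1] == pytest.approx(-1.25)

    def test_iteration_beyond_horizon_rejected(self, sched):
        with pytest.raises(ValueError):
            inertia_weight(301, sched)
        with pytest.raises(ValueError):
            acceleration_factors(-1, sched)


class TestParticleUpdates:
    def test_zero_attraction_keeps_velocity(self):
        v = np.array([0.2, -0.1])
        x = np.array([0.5, 0.5])
        out = update_velocity(v, x, x + 1, x - 1, w=1.0, c1=2.0, c2=2.0,
                              rng=FixedRng(0.0, 0.0))
        np.testing.assert_allclose(out, v)

    def test_at_both_attractors_velocity_only_decays(self):
        v = np.array([0.3])
        x = np.array([0.4])
        out = update_velocity(v, x, x, x, w=0.5, c1=2.0, c2=2.0,
                              rng=FixedRng(1.0, 1.0))
        np.testing.assert_allclose(out, 0.5 * v)

    def test_hand_computed_scalar_update_is_clamped(self):
        # 0.5*0.1 + 2*0.5*(0.5-0.3) + 1*1.0*(0.9-0.3) = 0.85 -> clamp 0.5
        out = update_velocity(np.array([0.1]), np.array([0.3]),
                              np.array([0.5]), np.array([0.9]),
                              w=0.5, c1=2.0, c2=1.0, rng=FixedRng(0.5, 1.0))
        assert out[0] == pytest.approx(0.5)

    def test_position_add_and_interior_case(self):
        x, v = update_position(np.array([0.3]), np.array([0.2]))
        assert x[0] == pytest.approx(0.5) and v[0] == pytest.approx(0.2)

    def test_boundary_clip_zeroes_velocity(self):
        x, v = update_position(np.array([0.9, 0.2]), np.array([0.5, -0.4]))
        np.testing.assert_allclose(x, [1.0, 0.0])
        np.testing.assert_allclose(v, [0.0, 0.0])

    def test_position_matches_add_then_clip_oracle(self, rng):
        p = rng.random(50)
        v = rng.uniform(-0.5, 0.5, 50)
        x, _ = update_position(p, v)
        np.testing.assert_allclose(x, np.clip(p + v, 0, 1))


class TestDecode:
    def test_threshold_selects_indices_above(self):
        idx = decode_particle(np.array([0.7, 0.2, 0.9]), 0.6)
        assert list(idx) == [0, 2]

    def test_empty_decode_repairs_to_argmax(self):
        idx = decode_particle(np.array([0.1, 0.5, 0.3]), 0.6)
        assert list(idx) == [1]

    def test_threshold_to_zero_selects_everything(self):
        idx = decode_particle(np.array([0.7, 0.2, 0.9]), 1e-9)
        assert list(idx) == [0, 1, 2]


class TestPbest:
    def _particle(self, obj):
        x = np.array([0.5])
        return Particle(x, np.zeros(1), x.copy(), obj, frozenset({0}))

    def test_dominating_candidate_replaces(self):
        p = self._particle((5, 2.0))
        update_pbest(p, (3, 1.0), {0}, np.random.default_rng(0))
        assert p.pbest_objectives == (3, 1.0)

    def test_dominated_candidate_kept_out(self):
        p = self._particle((3, 1.0))
        update_pbest(p, (5, 2.0), {0}, np.random.default_rng(0))
        assert p.pbest_objectives == (3, 1.0)

    def test_incomparable_candidate_accepted_half_the_time(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(10_000):
            p = self._particle((3, 2.0))
            update_pbest(p, (5, 1.0), {0}, rng)
            hits += p.pbest_objectives == (5, 1.0)
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)


class TestRunCmopso:
    def test_single_candidate_feature_forced_front(self, rng):
        X = rng.standard_normal((30, 1))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        cfg = RunConfig(iterations=5, pop_size=5, seed=0)
        res = run_cmopso(X, y, cfg)
        assert len(res.front) == 1
        assert res.front[0].objectives[0] == 1

    def test_same_seed_reproduces_front(self, small_dataset):
        y = small_dataset.y.values[:, 0]
        cfg = RunConfig(iterations=15, pop_size=10, seed=11)
        f1 = run_cmopso(small_dataset.X.values, y, cfg).front
        f2 = run_cmopso(small_dataset.X.values, y, cfg).front
        assert [(e.objectives, e.feature_indices) for e in f1] \
            == [(e.objectives, e.feature_indices) for e in f2]

    def test_front_is_non_dominated_and_within_bounds(self, small_dataset):
        y = small_dataset.y.values[:, 0]
        D = small_dataset.X.n_features
        cfg = RunConfig(iterations=20, pop_size=15, seed=2)
        res = run_cmopso(small_dataset.X.values, y, cfg)
        objs = [e.objectives for e in res.front]
        assert all(1 <= f1 <= D for f1, _ in objs)
        for i, p in enumerate(objs):
            assert not any(dominates(q, p) for j, q in enumerate(objs)
                           if j != i)

    def test_best_rmse_never_worsens_over_iterations(self, small_dataset):
        y = small_dataset.y.values[:, 0]
        cfg = RunConfig(iterations=25, pop_size=12, seed=5)
        res = run_cmopso(small_dataset.X.values, y, cfg)
        best = [f2 for _, f2 in res.history]
        assert all(a >= b - 1e-12 for a, b in zip(best, best[1:]))

    def test_frozen_dynamics_leave_front_at_initialization(self, small_dataset):
        # zero inertia and zero attraction: velocities stay 0, positions
        # never move, so iterating cannot change the archive
        y = small_dataset.y.values[:, 0]
        base = dict(iterations=1, pop_size=12, seed=9,
                    w_max=1e-9, w_min=0.0, c1i=0.0, c1f=0.0,
                    c2i=0.0, c2f=0.0)
        short = run_cmopso(small_dataset.X.values, y, RunConfig(**base))
        long = run_cmopso(small_dataset.X.values, y,
                          RunConfig(**{**base, "iterations": 10}))
        assert [e.objectives for e in short.front] \
            == [e.objectives for e in long.front]

    def test_full_candidate_subset_matches_stage1_rmse(self, small_dataset):
        y = small_dataset.y.values[:, 0]
        X = small_dataset.X.values
        cv = CvConfig(folds=10, pls_components=2, shuffle_seed=4)
        direct = kfold_pls_rmse(X, y, cv)
        obj = evaluate_particle(set(range(X.shape[1])), X, y, cv, cache={})
        assert obj == (X.shape[1], pytest.approx(direct))

    def test_memoized_evaluation_is_stable(self, small_dataset):
        y = small_dataset.y.values[:, 0]
        X = small_dataset.X.values
        cv = CvConfig(folds=5, pls_components=2, shuffle_seed=1)
        cache = {}
        a = evaluate_particle({0, 3, 5}, X, y, cv, cache)
        b = evaluate_particle({5, 0, 3}, X, y, cv, cache)
        assert a == b and len(cache) == 1

    def test_recovers_planted_signal_from_small_candidate_set(self):
        # 3 relevant + 3 noisy duplicates + 14 noise in the candidate set:
        # some front member should carry all 3 relevant and <=1 duplicate
        # in at least 8 of 10 seeded runs
        from swarmselect import SyntheticSpec, generate
        hits = 0
        for seed in range(1, 11):
            ds = generate(SyntheticSpec(60, 3, 3, 14, noise_sd=0.5,
                                        seed=seed))
            cfg = RunConfig(iterations=100, pop_size=40, seed=seed)
            res = run_cmopso(ds.X.values, ds.y.values[:, 0], cfg)
            hits += any(
                len(set(e.feature_indices) & {0, 1, 2}) == 3
                and len(set(e.feature_indices) & {3, 4, 5}) <= 1
                for e in res.front)
        assert hits >= 8
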