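"""Inertia-weight schedules, swarm updates and the optimizer loop."""

import numpy as np
import pytest

from mklsvm_pso import SCHEDULES, FitnessTrace, SwarmConfig, inertia_weight, pso_optimize
from mklsvm_pso.pso import SwarmState, update_position, update_velocity

DYNAMIC = [s for s in SCHEDULES if s != "constant"]


def _cfg(**kw):
    defaults = dict(n=4, dim=2, maxgen=100, bounds=((-1.0, 1.0), (-1.0, 1.0)), seed=0)
    defaults.update(kw)
    return SwarmConfig(**defaults)


class TestInertiaWeight:
    def test_constant_is_one(self):
        cfg = _cfg(schedule="constant")
        assert all(inertia_weight("constant", k, cfg) == 1.0 for k in (0, 50, 100))

    @pytest.mark.parametrize("schedule", DYNAMIC)
    def test_dynamic_start_at_omega_start(self, schedule):
        cfg = _cfg(schedule=schedule)
        assert inertia_weight(schedule, 0, cfg) == pytest.approx(0.9, abs=1e-12)

    def test_linear_midpoint_and_end(self):
        cfg = _cfg()
        for s in ("lin_a", "lin_b"):
            assert inertia_weight(s, 50, cfg) == pytest.approx(0.65)
            assert inertia_weight(s, 100, cfg) == pytest.approx(0.4)

    def test_quadratic_midpoints(self):
        cfg = _cfg()
        assert inertia_weight("quad_late", 50, cfg) == pytest.approx(0.9 - 0.5 * 0.25)
        assert inertia_weight("quad_early", 50, cfg) == pytest.approx(0.9 - 0.5 * 0.75)
        assert inertia_weight("quad_late", 100, cfg) == pytest.approx(0.4)
        assert inertia_weight("quad_early", 100, cfg) == pytest.approx(0.4)

    def test_exp_ratio_endpoints(self):
        cfg = _cfg(c_exp=10.0)
        assert inertia_weight("exp_ratio", 0, cfg) == pytest.approx(0.9, abs=1e-12)
        # never reaches omega_end: 0.4 * 2.25**(1/11)
        assert inertia_weight("exp_ratio", 100, cfg) == pytest.approx(
            0.4306025366396295, abs=1e-12
        )

    def test_schedule_ordering_between_endpoints(self):
        """quad_late > linear > quad_early strictly inside (0, T_max)."""
        cfg = _cfg()
        for k in range(1, 100):
            late = inertia_weight("quad_late", k, cfg)
            lin = inertia_weight("lin_a", k, cfg)
            early = inertia_weight("quad_early", k, cfg)
            assert late > lin > early

    @pytest.mark.parametrize("schedule", DYNAMIC)
    def test_dynamic_schedules_monotone_nonincreasing(self, schedule):
        cfg = _cfg()
        w = [inertia_weight(schedule, k, cfg) for k in range(101)]
        assert all(a >= b for a, b in zip(w, w[1:]))
        assert min(w) >= cfg.omega_end - 1e-12

    def test_unknown_schedule_and_range_errors(self):
        cfg = _cfg()
        with pytest.raises(ValueError):
            inertia_weight("cubic", 1, cfg)
        with pytest.raises(ValueError):
            inertia_weight("lin_a", 101, cfg)
        with pytest.raises(ValueError):
            SwarmConfig(n=4, dim=1, maxgen=10, bounds=((0.0, 1.0),), schedule="bogus")


def _state(cfg, X=None, V=None):
    X = np.zeros((cfg.n, cfg.dim)) if X is None else X
    V = np.zeros((cfg.n, cfg.dim)) if V is None else V
    return SwarmState(
        positions=X.copy(),
        velocities=V.copy(),
        pbest_positions=X.copy(),
        pbest_fitness=np.zeros(cfg.n),
        gbest_position=X[0].copy(),
        gbest_fitness=0.0,
    )


class TestUpdates:
    def test_velocity_unchanged_at_coincident_bests(self):
        cfg = _cfg()
        V0 = np.full((cfg.n, cfg.dim), 0.1)
        state = _state(cfg, V=V0)
        v = update_velocity(state, omega=1.0, cfg=cfg, rng=np.random.default_rng(0))
        assert np.allclose(v, V0)

    def test_zero_coefficients_give_zero_velocity(self):
        cfg = _cfg(c1=0.0, c2=0.0)
        state = _state(cfg, X=np.full((cfg.n, cfg.dim), 0.3), V=np.ones((cfg.n, cfg.dim)))
        state.pbest_positions += 1.0  # nonzero attraction that must vanish
        v = update_velocity(state, omega=0.0, cfg=cfg, rng=np.random.default_rng(0))
        assert np.allclose(v, 0.0)

    def test_velocity_clamped_to_vmax(self):
        cfg = _cfg()
        state = _state(cfg, X=np.full((cfg.n, cfg.dim), -1.0))
        state.pbest_positions[:] = 1.0
        state.gbest_position[:] = 1.0
        v = update_velocity(state, omega=1.0, cfg=cfg, rng=np.random.default_rng(1))
        assert np.all(np.abs(v) <= cfg.vmax_arr + 1e-15)

    def test_position_zero_velocity_noop(self):
        cfg = _cfg()
        state = _state(cfg, X=np.full((cfg.n, cfg.dim), 0.25))
        x = update_position(state, cfg)
        assert np.allclose(x, 0.25)

    def test_boundary_clamp_zeroes_velocity(self):
        cfg = _cfg()
        X = np.full((cfg.n, cfg.dim), 1.0)  # at upper bound
        V = np.full((cfg.n, cfg.dim), 0.2)  # pushing out
        state = _state(cfg, X=X, V=V)
        x = update_position(state, cfg)
        assert np.allclose(x, 1.0)
        assert np.allclose(state.velocities, 0.0)

    def test_interior_move_is_exact_addition(self):
        cfg = _cfg()
        X = np.full((cfg.n, cfg.dim), 0.1)
        V = np.full((cfg.n, cfg.dim), 0.05)
        state = _state(cfg, X=X, V=V)
        x = update_position(state, cfg)
        assert np.allclose(x, 0.15)
        assert np.allclose(state.velocities, 0.05)


class TestOptimizer:
    def test_deterministic_given_seed(self):
        cfg = _cfg(schedule="lin_a", maxgen=30)
        fn = lambda x: -float(np.sum(x**2))
        p1, f1, t1 = pso_optimize(fn, cfg)
        p2, f2, t2 = pso_optimize(fn, cfg)
        assert np.array_equal(p1, p2) and f1 == f2
        assert np.array_equal(t1.v_best, t2.v_best)
        assert np.array_equal(t1.v_ave, t2.v_ave)

    def test_constant_fitness_trace(self):
        cfg = _cfg(schedule="constant", maxgen=20)
        _, fit, trace = pso_optimize(lambda x: 42.0, cfg)
        assert fit == 42.0
        assert np.all(trace.v_best == 42.0)
        assert np.all(trace.v_ave == 42.0)

    def test_vbest_running_max_dominates_vave(self):
        cfg = _cfg(schedule="quad_late", maxgen=50, seed=7)
        _, _, trace = pso_optimize(lambda x: -float(np.sum(x**2)), cfg)
        assert np.all(np.diff(trace.v_best) >= 0)
        assert np.all(trace.v_best >= trace.v_ave - 1e-12)
        assert len(trace) == 50

    def test_never_evaluates_outside_bounds(self):
        cfg = _cfg(schedule="lin_b", maxgen=40, seed=3)
        lo, hi = cfg.lower, cfg.upper

        def fn(x):
            assert np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12)
            return float(x.sum())

        pso_optimize(fn, cfg)

    def test_fitness_failure_reports_context(self):
        cfg = _cfg(maxgen=5)

        def bad(x):
            raise FloatingPointError("boom")

        with pytest.raises(RuntimeError, match="generation 0"):
            pso_optimize(bad, cfg)

    def test_quadratic_recovery_single_schedule(self):
        """Short smoke version of the functional benchmark (full version in
        the acceptance suite): quad_late localizes a 3-D quadratic max."""
        target = np.array([0.3, -0.4, 0.1])
        cfg = SwarmConfig(
            n=20, dim=3, maxgen=100, schedule="quad_late",
            bounds=((-1.0, 1.0),) * 3, seed=5,
        )
        pos, _, _ = pso_optimize(lambda x: -float(np.sum((x - target) ** 2)), cfg)
        assert np.linalg.norm(pos - target) < 1e-2


def test_trace_round_trip(tmp_path):
    trace = FitnessTrace(
        v_best=[90.0, 93.0, 93.0], v_ave=[85.0, 90.0, 92.0], omega=[0.9, 0.7, 0.4]
    )
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    back = FitnessTrace.from_csv(path)
    assert np.allclose(back.v_best, trace.v_best)
    assert np.allclose(back.v_ave, trace.v_ave)
    assert np.allclose(back.omega, trace.omega)
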