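"""RDPSO: Laplace sampling, swarm update semantics, convergence, stability."""

import numpy as np
import pytest
import scipy.stats

from driftfit import (
    FunctionProblem,
    RdpsoConfig,
    SwarmState,
    boundedness_probe,
    local_attractor,
    mean_best,
    rdpso_optimize,
    rdpso_step,
    sample_phi,
)
from conftest import ScriptedRng


def sphere_problem(dim=2, half_width=10.0):
    return FunctionProblem(
        lambda x: float((x**2).sum()),
        np.full(dim, -half_width),
        np.full(dim, half_width),
    )


class TestSamplePhi:
    def test_u_one_gives_zero(self):
        assert sample_phi(ScriptedRng([1.0, 0.2])) == 0.0
        assert sample_phi(ScriptedRng([1.0, 0.9])) == 0.0

    def test_sign_and_magnitude(self):
        assert sample_phi(ScriptedRng([np.exp(-1.0), 0.9])) == pytest.approx(1.0)
        assert sample_phi(ScriptedRng([np.exp(-2.0), 0.1])) == pytest.approx(-2.0)

    def test_laplace_distribution(self):
        rng = np.random.default_rng(42)
        draws = sample_phi(rng, 100_000)
        assert draws.var() == pytest.approx(2.0, rel=0.05)  # Laplace(0,1) var
        assert abs(np.mean(draws > 0) - 0.5) < 0.01
        _, pvalue = scipy.stats.kstest(draws, "laplace")
        assert pvalue > 0.01

    def test_thermal_component_scale(self):
        """Thermal velocity α·|C−X|·φ at fixed |C−X| = c has std α·c·√2."""
        alpha, c = 0.75, 2.0
        rng = np.random.default_rng(7)
        thermal = alpha * c * sample_phi(rng, 200_000)
        assert thermal.std() == pytest.approx(alpha * c * np.sqrt(2), rel=0.02)


class TestMeanBest:
    def test_identical_pbests(self):
        q = np.array([1.5, -2.0])
        assert np.array_equal(mean_best(np.tile(q, (5, 1))), q)

    def test_two_particle_average(self):
        assert mean_best(np.array([[0.0], [2.0]]))[0] == 1.0

    def test_reorder_invariance(self):
        rng = np.random.default_rng(0)
        P = rng.random((7, 3))
        perm = rng.permutation(7)
        np.testing.assert_allclose(mean_best(P), mean_best(P[perm]))

    def test_empty_swarm_rejected(self):
        with pytest.raises(ValueError):
            mean_best(np.empty((0, 3)))


class TestLocalAttractor:
    def test_endpoints(self):
        pb, g = np.array([2.0]), np.array([-4.0])
        assert local_attractor(pb, g, ScriptedRng([1.0]))[0] == 2.0
        assert local_attractor(pb, g, ScriptedRng([0.0]))[0] == -4.0

    def test_coincident_points_fixed(self):
        g = np.array([3.0, -1.0])
        out = local_attractor(g.copy(), g, np.random.default_rng(0))
        assert np.array_equal(out, g)

    def test_convexity(self):
        rng = np.random.default_rng(5)
        pb, g = rng.normal(size=4), rng.normal(size=4)
        p = local_attractor(pb, g, rng)
        assert np.all(p >= np.minimum(pb, g)) and np.all(p <= np.maximum(pb, g))


class TestRdpsoStep:
    def _fresh_state(self, X):
        X = np.asarray(X, float)
        return SwarmState(
            X=X.copy(),
            V=np.zeros_like(X),
            pbest=X.copy(),
            pbest_f=np.full(X.shape[0], np.inf),
            gbest=X[0].copy(),
            gbest_f=np.inf,
        )

    def test_hand_computed_trace(self):
        """One iteration on a 2-particle 1-D sphere, replayed against an
        explicit hand evaluation of the update equations on the same
        recorded RNG stream."""
        problem = sphere_problem(dim=1)
        cfg = RdpsoConfig(m=2, alpha=0.5, beta=1.0, vmax=100.0, max_iter=1, seed=0)
        state = self._fresh_state([[2.0], [-3.0]])

        # recorded stream: per particle φ'(attractor), u, s
        rec = np.random.default_rng(123)
        a0, u0, s0 = rec.random(1)[0], rec.random(1)[0], rec.random(1)[0]
        a1, u1, s1 = rec.random(1)[0], rec.random(1)[0], rec.random(1)[0]

        C = (2.0 + -3.0) / 2.0
        # particle 0: f(2)=4 → pbest=2, gbest=2; attractor = 2 (pbest == gbest)
        phi0 = np.log(1.0 / u0) if s0 > 0.5 else -np.log(1.0 / u0)
        v0 = 0.5 * abs(C - 2.0) * phi0 + 1.0 * (2.0 - 2.0)
        x0 = 2.0 + v0
        # particle 1: f(-3)=9 → pbest=-3; gbest stays 2
        p1 = a1 * -3.0 + (1.0 - a1) * 2.0
        phi1 = np.log(1.0 / u1) if s1 > 0.5 else -np.log(1.0 / u1)
        v1 = 0.5 * abs(C - -3.0) * phi1 + 1.0 * (p1 - -3.0)
        x1 = -3.0 + v1

        rdpso_step(state, cfg, problem, np.random.default_rng(123))
        assert state.C[0] == C
        assert state.eval_count == 2 and state.k == 1
        assert state.pbest_f.tolist() == [4.0, 9.0]
        assert state.gbest_f == 4.0 and state.gbest[0] == 2.0
        assert state.V[:, 0].tolist() == [v0, v1]
        assert state.X[:, 0].tolist() == [x0, x1]
        del a0  # particle 0's attractor draw is consumed but irrelevant

    def test_pure_drift_jumps_to_attractor(self):
        """With α=0 and β=1 the position update lands exactly on the local
        attractor."""
        problem = sphere_problem(dim=1)
        cfg = RdpsoConfig(m=2, alpha=0.0, beta=1.0, vmax=100.0, max_iter=1, seed=0)
        state = self._fresh_state([[2.0], [-3.0]])
        rec = np.random.default_rng(9)
        a0 = rec.random(1)[0]
        rec.random(1), rec.random(1)
        a1 = rec.random(1)[0]
        p1 = a1 * -3.0 + (1.0 - a1) * 2.0
        rdpso_step(state, cfg, problem, np.random.default_rng(9))
        assert state.X[0, 0] == 2.0  # pbest == gbest == attractor
        assert state.X[1, 0] == p1

    def test_converged_swarm_is_stationary(self):
        problem = sphere_problem(dim=2)
        cfg = RdpsoConfig(m=3, alpha=0.0, beta=1.0, vmax=100.0, max_iter=1, seed=0)
        q = np.array([1.0, -2.0])
        state = self._fresh_state(np.tile(q, (3, 1)))
        rng = np.random.default_rng(0)
        for _ in range(5):
            rdpso_step(state, cfg, problem, rng)
        assert np.all(state.X == q)
        assert np.all(state.V == 0.0)

    def test_velocity_clamped_to_vmax(self):
        problem = sphere_problem(dim=1)
        cfg = RdpsoConfig(m=2, alpha=0.0, beta=1.0, vmax=0.01, max_iter=1, seed=0)
        state = SwarmState(
            X=np.array([[-9.0], [-9.0]]),
            V=np.zeros((2, 1)),
            pbest=np.array([[9.0], [9.0]]),
            pbest_f=np.array([-1.0, -1.0]),  # never improved: attractor stays 9
            gbest=np.array([9.0]),
            gbest_f=-1.0,
        )
        rdpso_step(state, cfg, problem, np.random.default_rng(0))
        assert np.all(state.V == 0.01)  # 18 requested, clamped

    def test_swarm_invariants_after_each_step(self, case1_problem):
        cfg = RdpsoConfig(m=8, alpha=0.75, beta=1.0, max_iter=1, seed=4)
        rng = np.random.default_rng(cfg.seed)
        from driftfit.rdpso import _init_positions, _resolve_vmax

        X = _init_positions(case1_problem, cfg.m, rng)
        state = self._fresh_state(X)
        vmax = _resolve_vmax(cfg, case1_problem.lower, case1_problem.upper)
        last_g = np.inf
        for _ in range(10):
            pbest_at_sweep_start = state.pbest.copy()
            rdpso_step(state, cfg, case1_problem, rng)
            assert state.gbest_f == state.pbest_f.min()
            # C is the centroid of the pbests as of the start of the sweep
            np.testing.assert_allclose(state.C, pbest_at_sweep_start.mean(axis=0))
            assert np.all(np.abs(state.V) <= vmax)
            assert np.all(state.X >= case1_problem.lower)
            assert np.all(state.X <= case1_problem.upper)
            assert state.gbest_f <= last_g
            last_g = state.gbest_f


class TestRdpsoOptimize:
    def test_sphere_convergence_rate(self):
        problem = sphere_problem(dim=2)
        wins = sum(
            rdpso_optimize(problem, RdpsoConfig(m=20, max_iter=200, seed=s)).best_J
            < 1e-6
            for s in range(20)
        )
        assert wins >= 19

    def test_seeded_determinism(self):
        problem = sphere_problem(dim=3)
        cfg = RdpsoConfig(m=10, max_iter=50, seed=11)
        a = rdpso_optimize(problem, cfg)
        b = rdpso_optimize(problem, cfg)
        assert a.best_J == b.best_J
        assert np.array_equal(a.best_theta, b.best_theta)
        assert np.array_equal(a.curve, b.curve)

    def test_curve_monotone_and_consistent(self):
        res = rdpso_optimize(sphere_problem(), RdpsoConfig(m=10, max_iter=80, seed=2))
        assert np.all(np.diff(res.curve) <= 0)
        assert res.best_J == res.curve[-1] == res.curve.min()
        assert res.eval_count == 10 * 80

    def test_zero_iterations_returns_initial_best(self):
        problem = sphere_problem(dim=2)
        res = rdpso_optimize(problem, RdpsoConfig(m=15, max_iter=0, seed=3))
        assert res.eval_count == 15
        assert res.curve.shape == (1,)
        assert res.best_J == problem.evaluate(res.best_theta)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RdpsoConfig(m=1)
        with pytest.raises(ValueError):
            RdpsoConfig(alpha=-0.1)
        with pytest.raises(ValueError):
            RdpsoConfig(vmax=0.0)


class TestBoundednessProbe:
    def test_pure_drift_collapses_to_origin(self):
        out = boundedness_probe(alpha=0.0, beta=1.0, iters=50, seed=0)
        # first update sends x0=0.1 to ~0; thereafter it stays at ~0
        assert np.all(out < 1e-12)

    def test_bounded_regime(self):
        for seed in range(5):
            out = boundedness_probe(alpha=1.0, beta=1.5, iters=1000, seed=seed)
            assert out.max() < 1e6

    def test_divergent_regime(self):
        exceed = sum(
            boundedness_probe(alpha=1.8, beta=1.5, iters=1000, seed=s).max() > 1e6
            for s in range(5)
        )
        assert exceed >= 3

    def test_regime_separation_orders_of_magnitude(self):
        bounded = np.median(
            [boundedness_probe(1.0, 1.5, 1000, s).max() for s in range(7)]
        )
        divergent = np.median(
            [boundedness_probe(1.8, 1.5, 1000, s).max() for s in range(7)]
        )
        assert divergent > 1e3 * bounded
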