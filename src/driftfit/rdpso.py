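"""Random drift particle swarm optimization (RDPSO), Laplace-thermal variant.

Each particle is modelled on a free electron in a conductor under an
external field: its velocity is the superposition of a *thermal* (random)
component and a *drift* (directed) component,

    V_{i,j} = α·|C_j − X_{i,j}|·φ_{i,j}  +  β·(p_{i,j} − X_{i,j})
    X_{i,j} ← X_{i,j} + V_{i,j}

where

* φ is Laplace(0, 1)-distributed, sampled as ±ln(1/u) with u, s ~ U(0,1)
  (sign from s > 0.5) — the heavy tail gives occasional long exploratory
  jumps;
* C is the *mean best* position, the arithmetic mean of all particles'
  personal bests, so the thermal scale α·|C−X| adapts to swarm spread and
  vanishes as the swarm converges;
* p is the particle's stochastic *local attractor*
  p_{i,j} = φ'·Pbest_{i,j} + (1−φ')·G_j with φ' ~ U(0,1), a random convex
  combination of the personal best and the global best toward which the
  drift pulls.

α (thermal coefficient) and β (drift coefficient) play the role of PSO's
inertia weight and acceleration coefficients; the benchmark protocol uses
α = 0.75, β = 1.0 with population 100.  Velocities are clamped elementwise
to ±Vmax and positions to the search box.

The iteration follows the benchmark procedure literally: the mean best is
computed once per iteration from the current personal bests, then each
particle in index order is evaluated, its personal/global bests updated,
and only then moved — so a particle's move already sees improvements found
earlier in the same sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experiment import RunResult

__all__ = [
    "RdpsoConfig",
    "SwarmState",
    "sample_phi",
    "mean_best",
    "local_attractor",
    "rdpso_step",
    "rdpso_optimize",
    "boundedness_probe",
]


@dataclass(frozen=True)
class RdpsoConfig:
    """RDPSO settings.  ``vmax=None`` defaults to 0.5·(upper−lower)."""

    m: int = 100
    alpha: float = 0.75
    beta: float = 1.0
    vmax: float | np.ndarray | None = None
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("population size m must be >= 2")
        if self.alpha < 0 or self.beta <= 0:
            raise ValueError("alpha must be >= 0 and beta > 0")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.vmax is not None and np.any(np.asarray(self.vmax) <= 0):
            raise ValueError("vmax must be > 0")


@dataclass
class SwarmState:
    """Mutable swarm state at iteration ``k``."""

    X: np.ndarray          # (m, D) positions
    V: np.ndarray          # (m, D) velocities
    pbest: np.ndarray      # (m, D) personal-best positions
    pbest_f: np.ndarray    # (m,) personal-best fitnesses
    gbest: np.ndarray      # (D,) global-best position
    gbest_f: float
    k: int = 0
    eval_count: int = 0
    C: np.ndarray = field(default=None)  # mean-best of the last step


def sample_phi(rng: np.random.Generator, size: int | None = None):
    """Laplace(0, 1) draw(s): ±ln(1/u), sign positive iff s > 0.5.

    Draw order is u first, then s (vectorized: all u, then all s), which the
    swarm update relies on for reproducibility.
    """
    u = rng.random(size) if size is not None else rng.random()
    s = rng.random(size) if size is not None else rng.random()
    mag = np.log(1.0 / u)
    return np.where(s > 0.5, mag, -mag) if size is not None else (mag if s > 0.5 else -mag)


def mean_best(pbest_positions: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the personal-best positions, per dimension."""
    pbest_positions = np.asarray(pbest_positions, dtype=float)
    if pbest_positions.ndim != 2 or pbest_positions.shape[0] == 0:
        raise ValueError("expected a nonempty (m, D) array of pbest positions")
    return pbest_positions.mean(axis=0)


def local_attractor(
    pbest_i: np.ndarray, gbest: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random convex combination φ'·Pbest + (1−φ')·G, φ' ~ U(0,1) per dim."""
    phi = rng.random(pbest_i.shape[0])
    return phi * pbest_i + (1.0 - phi) * gbest


def _resolve_vmax(cfg, lower, upper):
    if cfg.vmax is None:
        return 0.5 * (upper - lower)
    return np.broadcast_to(np.asarray(cfg.vmax, float), lower.shape)


def rdpso_step(
    state: SwarmState,
    cfg: RdpsoConfig,
    problem,
    rng: np.random.Generator,
) -> SwarmState:
    """One full RDPSO iteration (evaluate-then-move sweep over particles).

    Per particle the RNG is consumed in fixed order: D uniforms for the
    attractor, then D uniforms (u) and D uniforms (s) for the thermal draw.
    """
    lower, upper = problem.lower, problem.upper
    vmax = _resolve_vmax(cfg, lower, upper)
    m, D = state.X.shape
    C = mean_best(state.pbest)
    state.C = C
    for i in range(m):
        fx = problem.evaluate(state.X[i])
        state.eval_count += 1
        if fx < state.pbest_f[i]:
            state.pbest[i] = state.X[i]
            state.pbest_f[i] = fx
        g = int(np.argmin(state.pbest_f))  # ties → lowest particle index
        state.gbest = state.pbest[g].copy()
        state.gbest_f = float(state.pbest_f[g])
        p_attr = local_attractor(state.pbest[i], state.gbest, rng)
        phi = sample_phi(rng, D)
        v = cfg.alpha * np.abs(C - state.X[i]) * phi + cfg.beta * (p_attr - state.X[i])
        np.clip(v, -vmax, vmax, out=v)
        state.V[i] = v
        state.X[i] = np.clip(state.X[i] + v, lower, upper)
    state.k += 1
    return state


def _init_positions(problem, m, rng):
    D = problem.lower.size
    u = rng.random((m, D))
    if getattr(problem, "init_scheme", "uniform") == "log-uniform":
        lo, hi = np.log10(problem.lower), np.log10(problem.upper)
        return 10.0 ** (lo + u * (hi - lo))
    return problem.lower + u * (problem.upper - problem.lower)


def _evaluate_all(problem, X):
    return np.array([problem.evaluate(x) for x in X])


def rdpso_optimize(problem, cfg: RdpsoConfig) -> RunResult:
    """Full RDPSO run: seeded initialization + ``max_iter`` iterations.

    Positions are initialized uniformly (or log-uniformly, per the problem's
    ``init_scheme``) within the bounds; personal bests start at the initial
    positions and are scored by the first iteration's evaluation sweep, so
    ``eval_count = m × max_iter`` exactly.  ``max_iter = 0`` scores the
    initial population once and returns its best member.
    """
    rng = np.random.default_rng(cfg.seed)
    X = _init_positions(problem, cfg.m, rng)
    D = X.shape[1]
    state = SwarmState(
        X=X,
        V=np.zeros_like(X),
        pbest=X.copy(),
        pbest_f=np.full(cfg.m, np.inf),
        gbest=X[0].copy(),
        gbest_f=np.inf,
    )
    config_echo = {
        "m": cfg.m, "alpha": cfg.alpha, "beta": cfg.beta,
        "max_iter": cfg.max_iter,
    }
    if cfg.max_iter == 0:
        state.pbest_f = _evaluate_all(problem, X)
        state.eval_count = cfg.m
        g = int(np.argmin(state.pbest_f))
        best_f = float(state.pbest_f[g])
        return RunResult(
            "rdpso", X[g].copy(), best_f, np.array([best_f]),
            cfg.seed, state.eval_count, config_echo,
        )
    curve = np.empty(cfg.max_iter)
    for k in range(cfg.max_iter):
        rdpso_step(state, cfg, problem, rng)
        curve[k] = state.gbest_f
    return RunResult(
        "rdpso", state.gbest.copy(), float(state.gbest_f), curve,
        cfg.seed, state.eval_count, config_echo,
    )


def boundedness_probe(
    alpha: float,
    beta: float,
    iters: int = 1000,
    seed: int = 0,
    x0: float = 0.1,
) -> np.ndarray:
    """1-D stability probe of the RDPSO update.

    The local attractor is fixed at the origin and the mean-best at 0.1; the
    single particle iterates the velocity/position update with no clamping
    and |X_k| is recorded (plot log|X_k| to see the bounded vs divergent
    regimes, e.g. α=1, β=1.5 bounded vs α=1.8, β=1.5 divergent).  Once |X|
    exceeds 1e300 the trajectory is frozen to avoid float overflow.
    """
    rng = np.random.default_rng(seed)
    x = float(x0)
    out = np.empty(iters)
    for k in range(iters):
        if abs(x) < 1e300:
            phi = sample_phi(rng)
            x = x + alpha * abs(0.1 - x) * phi + beta * (0.0 - x)
        out[k] = abs(x)
    return out
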