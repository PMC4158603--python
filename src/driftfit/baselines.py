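"""Comparison optimizers: canonical PSO, DE/rand/1/bin, (μ,λ)- and (μ+λ)-ES.

All baselines share the RDPSO problem interface (bounds, ``init_scheme``,
``evaluate``) and return the same :class:`~driftfit.experiment.RunResult`,
so repeated-run statistics and convergence curves are directly comparable
under matched evaluation budgets.

Benchmark settings: PSO with inertia w = 0.729 and c1 = c2 = 1.49; DE with
F = 0.5, CR = 0.55; ES with λ = 100, μ = 10, varphi = 1.  The ES mutation
operator is a non-adaptive isotropic Gaussian with per-dimension standard
deviation varphi·(upper−lower)/100 (the protocol fixes only varphi; no
self-adaptation or recombination is used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiment import RunResult
from .rdpso import _evaluate_all, _init_positions, _resolve_vmax, mean_best  # noqa: F401

__all__ = [
    "PsoConfig",
    "DeConfig",
    "EsConfig",
    "pso_optimize",
    "de_optimize",
    "es_optimize",
]


# --------------------------------------------------------------------------
# Canonical gbest-topology PSO
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PsoConfig:
    m: int = 100
    w: float = 0.729
    c1: float = 1.49
    c2: float = 1.49
    vmax: float | np.ndarray | None = None
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("population size m must be >= 2")
        if self.w <= 0 or self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("w, c1 and c2 must be > 0")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


def pso_optimize(problem, cfg: PsoConfig) -> RunResult:
    """Standard PSO: V ← w·V + c1·r·(P−X) + c2·R·(G−X), X ← X + V.

    r, R ~ U(0,1) fresh per dimension; velocities clamped to ±Vmax
    (default 0.5·(upper−lower)); positions clamped to the bounds.  Same
    evaluate-then-move sweep and eval accounting as RDPSO.
    """
    rng = np.random.default_rng(cfg.seed)
    lower, upper = problem.lower, problem.upper
    vmax = _resolve_vmax(cfg, lower, upper)
    X = _init_positions(problem, cfg.m, rng)
    m, D = X.shape
    V = np.zeros_like(X)
    pbest = X.copy()
    pbest_f = np.full(m, np.inf)
    gbest = X[0].copy()
    gbest_f = np.inf
    eval_count = 0
    config_echo = {"m": cfg.m, "w": cfg.w, "c1": cfg.c1, "c2": cfg.c2,
                   "max_iter": cfg.max_iter}
    if cfg.max_iter == 0:
        pbest_f = _evaluate_all(problem, X)
        g = int(np.argmin(pbest_f))
        return RunResult("pso", X[g].copy(), float(pbest_f[g]),
                         np.array([float(pbest_f[g])]), cfg.seed, m, config_echo)
    curve = np.empty(cfg.max_iter)
    for k in range(cfg.max_iter):
        for i in range(m):
            fx = problem.evaluate(X[i])
            eval_count += 1
            if fx < pbest_f[i]:
                pbest[i] = X[i]
                pbest_f[i] = fx
            g = int(np.argmin(pbest_f))
            gbest = pbest[g]
            gbest_f = float(pbest_f[g])
            r = rng.random(D)
            R = rng.random(D)
            v = cfg.w * V[i] + cfg.c1 * r * (pbest[i] - X[i]) + cfg.c2 * R * (gbest - X[i])
            np.clip(v, -vmax, vmax, out=v)
            V[i] = v
            X[i] = np.clip(X[i] + v, lower, upper)
        curve[k] = gbest_f
    g = int(np.argmin(pbest_f))
    return RunResult("pso", pbest[g].copy(), float(pbest_f[g]), curve,
                     cfg.seed, eval_count, config_echo)


# --------------------------------------------------------------------------
# Differential evolution, DE/rand/1/bin
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeConfig:
    m: int = 100
    F: float = 0.5
    CR: float = 0.55
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 4:
            raise ValueError("DE/rand/1 needs a population of at least 4")
        if not (0 < self.F <= 2):
            raise ValueError("F must be in (0, 2]")
        if not (0 <= self.CR <= 1):
            raise ValueError("CR must be in [0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def _distinct_indices(rng, m, exclude):
    """Three distinct random indices, none equal to ``exclude`` (rejection)."""
    picked = []
    while len(picked) < 3:
        j = int(rng.integers(m))
        if j != exclude and j not in picked:
            picked.append(j)
    return picked


def de_optimize(problem, cfg: DeConfig) -> RunResult:
    """DE/rand/1/bin with greedy (≤) selection and synchronous generations.

    The initial-population evaluation counts as the first iteration, so
    ``eval_count = m × max_iter``.
    """
    rng = np.random.default_rng(cfg.seed)
    lower, upper = problem.lower, problem.upper
    X = _init_positions(problem, cfg.m, rng)
    m, D = X.shape
    f = _evaluate_all(problem, X)
    eval_count = m
    curve = np.empty(cfg.max_iter)
    curve[0] = f.min()
    config_echo = {"m": cfg.m, "F": cfg.F, "CR": cfg.CR, "max_iter": cfg.max_iter}
    for gen in range(1, cfg.max_iter):
        trial = np.empty_like(X)
        for i in range(m):
            r1, r2, r3 = _distinct_indices(rng, m, i)
            v = np.clip(X[r1] + cfg.F * (X[r2] - X[r3]), lower, upper)
            jrand = int(rng.integers(D))
            mask = rng.random(D) < cfg.CR
            mask[jrand] = True  # at least one mutant coordinate
            trial[i] = np.where(mask, v, X[i])
        f_trial = _evaluate_all(problem, trial)
        eval_count += m
        improved = f_trial <= f
        X[improved] = trial[improved]
        f[improved] = f_trial[improved]
        curve[gen] = min(curve[gen - 1], f.min())
    g = int(np.argmin(f))
    return RunResult("de", X[g].copy(), float(f[g]), curve, cfg.seed,
                     eval_count, config_echo)


# --------------------------------------------------------------------------
# Evolution strategies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EsConfig:
    lam: int = 100
    mu: int = 10
    varphi: float = 1.0
    mode: str = "comma"  # or "plus"
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("comma", "plus"):
            raise ValueError("mode must be 'comma' or 'plus'")
        if self.mu < 1 or self.lam < 1:
            raise ValueError("mu and lam must be >= 1")
        if self.mode == "comma" and self.mu >= self.lam:
            raise ValueError("(mu, lambda)-ES requires mu < lambda")
        if self.varphi <= 0:
            raise ValueError("varphi must be > 0")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


def es_optimize(problem, cfg: EsConfig) -> RunResult:
    """(μ,λ)- or (μ+λ)-ES with isotropic Gaussian mutation.

    Each generation draws λ offspring from uniformly chosen parents with
    per-dimension mutation std varphi·(upper−lower)/100, clamped to bounds.
    Survivors are the best μ of the offspring (comma) or of parents plus
    offspring (plus).  ``eval_count = μ + λ × max_iter`` (the initial
    parents are scored once).
    """
    rng = np.random.default_rng(cfg.seed)
    lower, upper = problem.lower, problem.upper
    sigma = cfg.varphi * (upper - lower) / 100.0
    parents = _init_positions(problem, cfg.mu, rng)
    f_par = _evaluate_all(problem, parents)
    eval_count = cfg.mu
    g = int(np.argmin(f_par))
    best_x = parents[g].copy()
    best_f = float(f_par[g])
    mode_name = f"es-{cfg.mode}"
    config_echo = {"lam": cfg.lam, "mu": cfg.mu, "varphi": cfg.varphi,
                   "mode": cfg.mode, "max_iter": cfg.max_iter}
    if cfg.max_iter == 0:
        return RunResult(mode_name, best_x, best_f, np.array([best_f]),
                         cfg.seed, eval_count, config_echo)
    D = parents.shape[1]
    curve = np.empty(cfg.max_iter)
    for gen in range(cfg.max_iter):
        idx = rng.integers(cfg.mu, size=cfg.lam)
        noise = rng.standard_normal((cfg.lam, D)) * sigma
        children = np.clip(parents[idx] + noise, lower, upper)
        f_child = _evaluate_all(problem, children)
        eval_count += cfg.lam
        if cfg.mode == "comma":
            order = np.argsort(f_child, kind="stable")[: cfg.mu]
            parents, f_par = children[order], f_child[order]
        else:
            pool = np.vstack([parents, children])
            f_pool = np.concatenate([f_par, f_child])
            order = np.argsort(f_pool, kind="stable")[: cfg.mu]
            parents, f_par = pool[order], f_pool[order]
        if f_par[0] < best_f:
            best_f = float(f_par[0])
            best_x = parents[0].copy()
        curve[gen] = best_f
    return RunResult(mode_name, best_x, best_f, curve, cfg.seed,
                     eval_count, config_echo)
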