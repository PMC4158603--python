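"""Evaluation harness: repeated seeded runs, J statistics and curves.

The benchmark protocol runs each optimizer ``n_runs`` times (20 in the
benchmark protocol) with distinct seeds and summarizes the final objective
values by their best, mean and sample standard deviation, alongside the
per-iteration best-so-far convergence curves averaged across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RunResult",
    "StatsSummary",
    "run_trials",
    "summarize",
    "average_convergence",
    "iterations_for_budget",
    "ALGORITHMS",
]

#: Registered optimizer names (resolved lazily to avoid import cycles).
ALGORITHMS = ("rdpso", "pso", "de", "es-comma", "es-plus")


@dataclass(frozen=True)
class RunResult:
    """One optimization trajectory.

    ``curve`` holds the best objective value found so far after each
    iteration, hence is non-increasing with ``best_J = curve[-1] =
    min(curve)``.
    """

    algorithm: str
    best_theta: np.ndarray
    best_J: float
    curve: np.ndarray
    seed: int
    eval_count: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_theta": [float(v) for v in self.best_theta],
            "best_J": float(self.best_J),
            "curve": [float(v) for v in self.curve],
            "seed": self.seed,
            "eval_count": self.eval_count,
            "config": self.config,
        }


@dataclass(frozen=True)
class StatsSummary:
    """Best / mean / sample-std of the final J over repeated runs."""

    best_J: float
    mean_J: float
    std_J: float
    n_runs: int
    seeds: tuple[int, ...]


def _get_optimizer(algorithm: str):
    from . import baselines, rdpso

    table = {
        "rdpso": rdpso.rdpso_optimize,
        "pso": baselines.pso_optimize,
        "de": baselines.de_optimize,
        "es-comma": baselines.es_optimize,
        "es-plus": baselines.es_optimize,
    }
    try:
        return table[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
        ) from None


def _make_config(algorithm: str, iters: int, seed: int, params: dict):
    from . import baselines, rdpso

    params = dict(params)
    if algorithm == "rdpso":
        return rdpso.RdpsoConfig(max_iter=iters, seed=seed, **params)
    if algorithm == "pso":
        return baselines.PsoConfig(max_iter=iters, seed=seed, **params)
    if algorithm == "de":
        return baselines.DeConfig(max_iter=iters, seed=seed, **params)
    mode = "comma" if algorithm == "es-comma" else "plus"
    return baselines.EsConfig(max_iter=iters, seed=seed, mode=mode, **params)


def iterations_for_budget(evaluations: int, population: int) -> int:
    """Iterations that spend an evaluation budget with a given population.

    The budget must be an exact multiple of the population (e.g. 2,250,000
    evaluations with population 100 → 22,500 iterations).
    """
    if evaluations % population != 0:
        raise ValueError(
            f"budget {evaluations} is not a multiple of the population {population}"
        )
    return evaluations // population


def run_trials(
    algorithm: str,
    problem,
    n_runs: int,
    iters: int,
    base_seed: int = 0,
    **params,
) -> list[RunResult]:
    """Run an optimizer ``n_runs`` times; run r uses seed = base_seed + r."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    optimize = _get_optimizer(algorithm)
    results = []
    for r in range(n_runs):
        cfg = _make_config(algorithm, iters, base_seed + r, params)
        results.append(optimize(problem, cfg))
    return results


def summarize(results: list[RunResult]) -> StatsSummary:
    """Best / mean / sample standard deviation of final J across runs."""
    if not results:
        raise ValueError("results must be nonempty")
    final = np.array([r.best_J for r in results])
    std = float(final.std(ddof=1)) if final.size > 1 else 0.0
    return StatsSummary(
        best_J=float(final.min()),
        mean_J=float(final.mean()),
        std_J=std,
        n_runs=len(results),
        seeds=tuple(r.seed for r in results),
    )


def average_convergence(results: list[RunResult]) -> np.ndarray:
    """Pointwise mean of the per-run best-so-far curves."""
    if not results:
        raise ValueError("results must be nonempty")
    lengths = {len(r.curve) for r in results}
    if len(lengths) != 1:
        raise ValueError(f"curves have unequal lengths: {sorted(lengths)}")
    return np.mean([r.curve for r in results], axis=0)


# --------------------------------------------------------------------------
# Serialization helpers
# --------------------------------------------------------------------------

def results_to_json(results: list[RunResult], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in results], indent=2)
    )


def summary_to_frame(summaries: dict[str, StatsSummary]) -> pd.DataFrame:
    """Benchmark-table layout: one column per algorithm, rows best/mean/std."""
    return pd.DataFrame(
        {
            name: {
                "best_J": s.best_J,
                "mean_J": s.mean_J,
                "std_J": s.std_J,
                "n_runs": s.n_runs,
            }
            for name, s in summaries.items()
        }
    )


def curves_to_frame(curves: dict[str, np.ndarray]) -> pd.DataFrame:
    """Averaged convergence curves, one column per algorithm plus iteration."""
    frame = pd.DataFrame(curves)
    frame.insert(0, "iteration", np.arange(1, len(frame) + 1))
    return frame
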