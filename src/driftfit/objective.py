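"""Weighted least-squares objective and the bounded problem definition.

The cost handed to every optimizer is the discretized weighted sum of
squared residuals

    J(θ) = Σ_experiments Σ_times Σ_observed  w_ij · (y_pred(θ) − y_obs)²

with y_pred from the fixed-step RK4 forward solve at θ.  Two weighting
schemes are supported:

``unit``
    every w_ij = 1 (the α-pinene protocol);

``inv_max_sq``
    w_ij = (1 / max_t |reference trajectory of variable j in experiment i|)²,
    normalizing the contribution of variables with very different scales
    (the three-step-pathway protocol).  The maxima are taken once from the
    noise-free nominal-model trajectories and frozen, so J stays a fixed
    function of θ.

A divergent forward solve maps to the large finite penalty ``PENALTY_J``
instead of raising, keeping the fitness ordering total for the optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from numba import njit

from . import models as _models
from .datagen import Dataset, add_noise, generate_noise_free
from .forward import _CASE_IDS, _rk4_kernel, rk4_integrate
from .models import ExperimentDesign, OdeModel, ParameterVector

__all__ = [
    "PENALTY_J",
    "WeightTable",
    "Problem",
    "FunctionProblem",
    "compute_weights",
    "objective_J",
    "build_problem",
    "problem_from_yaml",
]

#: Objective value assigned to a divergent (non-finite) forward solve.
PENALTY_J = 1e12


@dataclass(frozen=True)
class WeightTable:
    """Per-(experiment, observed-variable) nonnegative weights."""

    values: np.ndarray  # (n_experiments, n_observed)
    scheme: str = "unit"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("weights must be a 2-D (experiment × variable) table")
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("weights must be finite and >= 0")


def compute_weights(data: Dataset, scheme: str = "unit") -> WeightTable:
    """Weight table from a reference dataset.

    For ``inv_max_sq`` the reference should be the noise-free nominal-model
    dataset; weights are (1/max_t |value|)² per experiment and variable.
    """
    n_exp, _, n_var = data.values.shape
    if scheme == "unit":
        return WeightTable(np.ones((n_exp, n_var)), "unit")
    if scheme == "inv_max_sq":
        maxima = np.abs(data.values).max(axis=1)  # (n_exp, n_var)
        if (maxima == 0).any():
            i, j = np.argwhere(maxima == 0)[0]
            raise ValueError(
                "inv_max_sq undefined: max |value| is zero for experiment "
                f"{data.experiment_ids[i]}, variable {data.observed_states[j]}"
            )
        return WeightTable((1.0 / maxima) ** 2, "inv_max_sq")
    raise ValueError(f"unknown weighting scheme {scheme!r}")


# --------------------------------------------------------------------------
# Problem definitions
# --------------------------------------------------------------------------

@dataclass
class Problem:
    """A bounded weighted least-squares fitting problem.

    Exposes the minimal optimizer interface: ``lower``, ``upper``,
    ``init_scheme`` and ``evaluate(θ) -> J``.
    """

    model: OdeModel
    designs: list[ExperimentDesign]
    data: Dataset
    weights: WeightTable
    lower: np.ndarray
    upper: np.ndarray
    substeps: int = 20
    init_scheme: str = "uniform"  # or "log-uniform"
    _packed: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("bounds shape mismatch")
        if not (self.lower < self.upper).all():
            raise ValueError("lower bounds must be strictly below upper bounds")
        if self.init_scheme not in ("uniform", "log-uniform"):
            raise ValueError("init_scheme must be 'uniform' or 'log-uniform'")
        if self.init_scheme == "log-uniform" and (self.lower <= 0).any():
            raise ValueError("log-uniform initialization needs positive lower bounds")
        n_exp = len(self.designs)
        if self.data.values.shape[0] != n_exp:
            raise ValueError("data does not match the number of designs")
        if not np.array_equal(self.data.times, self.designs[0].sample_times):
            raise ValueError("data time grid does not match the designs")
        if self.weights.values.shape != self.data.values.shape[::2]:
            raise ValueError("weight table shape does not match the data")

    @property
    def dim(self) -> int:
        return self.lower.size

    def evaluate(self, theta: np.ndarray) -> float:
        return objective_J(theta, self)


class FunctionProblem:
    """Wrap a plain function f(θ) as an optimizer problem (test functions,
    custom objectives)."""

    def __init__(
        self,
        func: Callable[[np.ndarray], float],
        lower: np.ndarray,
        upper: np.ndarray,
        init_scheme: str = "uniform",
    ):
        self.func = func
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.init_scheme = init_scheme

    @property
    def dim(self) -> int:
        return self.lower.size

    def evaluate(self, theta: np.ndarray) -> float:
        return float(self.func(theta))


# --------------------------------------------------------------------------
# Objective evaluation
# --------------------------------------------------------------------------

@njit(cache=True, error_model="numpy")
def _objective_kernel(case_id, theta, x0, times, substeps, SP, data, w, penalty):
    total = 0.0
    n_exp = data.shape[0]
    for e in range(n_exp):
        states, diverged = _rk4_kernel(
            case_id, theta, x0, times, substeps, SP[e, 0], SP[e, 1]
        )
        if diverged:
            return penalty
        for t in range(data.shape[1]):
            for j in range(data.shape[2]):
                r = states[t, j] - data[e, t, j]
                total += w[e, j] * r * r
    if not np.isfinite(total):
        return penalty
    return total


def _pack(problem: Problem):
    if problem._packed is None:
        case_id = _CASE_IDS[problem.model.name]
        SP = np.zeros((len(problem.designs), 2))
        for i, d in enumerate(problem.designs):
            controls = dict(problem.model.controls)
            controls.update(d.controls)
            SP[i, 0] = controls.get("S", 0.0)
            SP[i, 1] = controls.get("P", 0.0)
        cols = np.array([s - 1 for s in problem.data.observed_states])
        if not np.array_equal(cols, np.arange(problem.model.state_dim)):
            raise ValueError("compiled path expects all states observed")
        problem._packed = (
            case_id,
            np.ascontiguousarray(problem.model.initial_state),
            np.ascontiguousarray(problem.data.times),
            SP,
            np.ascontiguousarray(problem.data.values),
            np.ascontiguousarray(problem.weights.values),
        )
    return problem._packed


def objective_J(theta: ParameterVector | np.ndarray, problem: Problem) -> float:
    """Weighted sum of squared residuals at θ (in-bounds θ expected).

    Divergent forward solves yield the finite penalty :data:`PENALTY_J`.
    """
    values = theta.values if isinstance(theta, ParameterVector) else np.asarray(theta, float)
    if values.shape != problem.lower.shape:
        raise ValueError(
            f"theta has shape {values.shape}, bounds have {problem.lower.shape}"
        )
    if problem.model.name in _CASE_IDS:
        case_id, x0, times, SP, data, w = _pack(problem)
        return float(
            _objective_kernel(
                case_id,
                np.ascontiguousarray(values),
                x0,
                times,
                problem.substeps,
                SP,
                data,
                w,
                PENALTY_J,
            )
        )
    # Generic path for plug-in models.
    total = 0.0
    cols = [s - 1 for s in problem.data.observed_states]
    for e, design in enumerate(problem.designs):
        traj = rk4_integrate(problem.model, values, design, problem.substeps)
        if traj.diverged:
            return PENALTY_J
        resid = traj.states[:, cols] - problem.data.values[e]
        total += float((problem.weights.values[e] * resid**2).sum())
    return total if np.isfinite(total) else PENALTY_J


# --------------------------------------------------------------------------
# Problem construction
# --------------------------------------------------------------------------

def build_problem(
    case: int,
    noise_sigma: float = 0.0,
    noise_seed: int = 0,
    substeps: int = 20,
    scheme: str | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    init_scheme: str | None = None,
) -> Problem:
    """Assemble a benchmark fitting problem.

    Defaults follow the benchmark protocol: case 1 uses unit weights and
    uniform initialization in [0, 1e-3]^5; case 2 uses inverse-max-squared
    weights (from the noise-free nominal trajectories) and log-uniform
    initialization in [1e-6, 1e2]^36.  The noise-free reference is always
    used for the weights, even when the fitted data are noisy.
    """
    designs = _models.experiment_grid(case)
    reference = generate_noise_free(case, designs, substeps)
    data = reference if noise_sigma == 0 else add_noise(reference, noise_sigma, noise_seed)
    if scheme is None:
        scheme = "unit" if case == 1 else "inv_max_sq"
    weights = compute_weights(reference, scheme)
    lo, hi = bounds if bounds is not None else _models.default_bounds(case)
    if init_scheme is None:
        init_scheme = "uniform" if case == 1 else "log-uniform"
    model = _models.get_model(_models.CASE_NAMES[case])
    return Problem(
        model=model,
        designs=designs,
        data=data,
        weights=weights,
        lower=lo,
        upper=hi,
        substeps=substeps,
        init_scheme=init_scheme,
    )


def problem_from_yaml(path: str | Path) -> Problem:
    """Build a Problem from a YAML config.

    Recognized keys: ``case`` (1 or 2) or equivalently ``model``
    ("alpha_pinene" / "three_step"), plus ``noise_sigma``, ``noise_seed``,
    ``substeps``, ``scheme``, ``init_scheme``, and
    ``bounds: {lower: [...] | scalar, upper: [...] | scalar}``.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if "case" in cfg:
        case = cfg["case"]
    else:
        by_name = {name: case for case, name in _models.CASE_NAMES.items()}
        case = by_name[cfg["model"]]
    bounds = None
    if "bounds" in cfg:
        dim = 5 if case == 1 else 36
        lo = np.broadcast_to(np.asarray(cfg["bounds"]["lower"], float), (dim,)).copy()
        hi = np.broadcast_to(np.asarray(cfg["bounds"]["upper"], float), (dim,)).copy()
        bounds = (lo, hi)
    return build_problem(
        case,
        noise_sigma=float(cfg.get("noise_sigma", 0.0)),
        noise_seed=int(cfg.get("noise_seed", 0)),
        substeps=int(cfg.get("substeps", 20)),
        scheme=cfg.get("scheme"),
        bounds=bounds,
        init_scheme=cfg.get("init_scheme"),
    )
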