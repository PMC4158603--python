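"""Benchmark kinetic models for the parameter-estimation (inverse) problem.

Two classic systems-biology calibration benchmarks are built in:

``alpha_pinene``
    Thermal isomerization of α-pinene: a closed, linear first-order reaction
    network with five states (α-pinene, dipentene, alloocimen, β-pyronene and
    a dimer, concentrations in percent) and five unknown rate constants
    p1..p5.

``three_step``
    A three-step gene/enzyme/metabolite cascade: three mRNA species G1..G3
    under Hill-type repression by the pathway product P and activation by an
    upstream metabolite, three enzymes E1..E3 produced by Michaelis–Menten
    kinetics from their transcripts, and two intermediate metabolites M1, M2
    connected by reversible Michaelis–Menten fluxes from substrate S to
    product P.  S and P are held fixed within an experiment; 36 kinetic
    parameters θ1..θ36 are unknown.

Both models ship with nominal ("true") parameter values used to generate
pseudo-experimental data, default initial states, sample-time grids, search
bounds, and — for the three-step pathway — the 4×4 grid of (S, P) levels
defining 16 pseudo-experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterVector",
    "OdeModel",
    "ExperimentDesign",
    "alpha_pinene_rhs",
    "three_step_rhs",
    "nominal_parameters",
    "default_bounds",
    "experiment_grid",
    "get_model",
    "MODEL_REGISTRY",
    "CASE_NAMES",
]

# --------------------------------------------------------------------------
# Nominal values, initial states, grids, bounds
# --------------------------------------------------------------------------

#: Nominal rate constants (p1..p5) for the α-pinene network, in 1/min.
CASE1_NOMINAL = np.array([5.93e-5, 2.96e-5, 2.05e-5, 27.5e-5, 4.00e-5])

#: Initial state for α-pinene: pure α-pinene at 100%.  The benchmark is
#: conventionally run from pure reactant; concentrations are percentages.
CASE1_X0 = np.array([100.0, 0.0, 0.0, 0.0, 0.0])

#: Classical α-pinene measurement times (min).
CASE1_SAMPLE_TIMES = np.array(
    [1230.0, 3060.0, 4920.0, 7800.0, 10680.0, 15030.0, 22620.0, 36420.0]
)

#: Default search box for the α-pinene rate constants.
CASE1_BOUNDS = (np.zeros(5), np.full(5, 1e-3))

#: θ-index → parameter-name mapping for the three-step pathway, frozen in
#: decision-vector order (θ1..θ36).
CASE2_PARAM_NAMES = (
    "V1", "Ki1", "ni1", "Ka1", "na1", "k1",
    "V2", "Ki2", "ni2", "Ka2", "na2", "k2",
    "V3", "Ki3", "ni3", "Ka3", "na3", "k3",
    "V4", "K4", "k4",
    "V5", "K5", "k5",
    "V6", "K6", "k6",
    "kcat1", "Km1", "Km2",
    "kcat2", "Km3", "Km4",
    "kcat3", "Km5", "Km6",
)

#: Nominal values for θ1..θ36 of the three-step pathway.
CASE2_NOMINAL = np.array(
    [
        1.0, 1.0, 2.0, 1.0, 2.0, 1.0,   # V1, Ki1, ni1, Ka1, na1, k1
        1.0, 1.0, 2.0, 1.0, 2.0, 1.0,   # V2, Ki2, ni2, Ka2, na2, k2
        1.0, 1.0, 2.0, 1.0, 2.0, 1.0,   # V3, Ki3, ni3, Ka3, na3, k3
        0.1, 1.0, 0.1,                  # V4, K4, k4
        0.1, 1.0, 0.1,                  # V5, K5, k5
        0.1, 1.0, 0.1,                  # V6, K6, k6
        1.0, 1.0, 1.0,                  # kcat1, Km1, Km2
        1.0, 1.0, 1.0,                  # kcat2, Km3, Km4
        1.0, 1.0, 1.0,                  # kcat3, Km5, Km6
    ]
)

#: State ordering for the three-step pathway, frozen.
CASE2_STATE_NAMES = ("G1", "G2", "G3", "E1", "E2", "E3", "M1", "M2")

#: Default initial state for the three-step pathway (all species at 0.1).
#: The benchmark description leaves x0 open; a small uniform positive level
#: keeps every Hill/Michaelis–Menten term well defined at t=0.
CASE2_X0 = np.full(8, 0.1)

#: Default sampling grid: 21 uniform samples on [0, 120] time units.
CASE2_SAMPLE_TIMES = np.linspace(0.0, 120.0, 21)

#: Default search box for the three-step pathway (log-uniform initialization).
CASE2_BOUNDS = (np.full(36, 1e-6), np.full(36, 1e2))

#: Substrate / product levels of the 16-experiment design grid.
CASE2_S_LEVELS = (0.1, 0.46416, 2.1544, 10.0)
CASE2_P_LEVELS = (0.05, 0.13572, 0.36840, 1.0)

CASE_NAMES = {1: "alpha_pinene", 2: "three_step"}


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterVector:
    """A point θ in a box-bounded parameter space θL ≤ θ ≤ θU."""

    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if values.ndim != 1 or lower.shape != values.shape or upper.shape != values.shape:
            raise ValueError("values, lower and upper must be 1-D with equal length")
        if not (np.isfinite(values).all() and np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("ParameterVector entries must be finite")
        if not (lower < upper).all():
            raise ValueError("lower bounds must be strictly below upper bounds")
        if (values < lower).any() or (values > upper).any():
            raise ValueError("values violate bounds")

    def __len__(self) -> int:
        return self.values.size

    def replace(self, values: np.ndarray) -> "ParameterVector":
        """New ParameterVector with the same bounds and different values."""
        return ParameterVector(np.asarray(values, dtype=float), self.lower, self.upper)

    def clip(self, values: np.ndarray) -> np.ndarray:
        """Clamp an arbitrary array into this vector's box."""
        return np.clip(np.asarray(values, dtype=float), self.lower, self.upper)


@dataclass(frozen=True)
class OdeModel:
    """A parametric ODE system dx/dt = rhs(x, θ, controls, t).

    ``controls`` holds fixed, non-estimated quantities (the three-step
    pathway's S and P); an :class:`ExperimentDesign` overrides them per
    experiment.
    """

    name: str
    state_dim: int
    rhs: Callable[[np.ndarray, np.ndarray, Mapping[str, float], float], np.ndarray]
    initial_state: np.ndarray
    controls: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        x0 = np.asarray(self.initial_state, dtype=float)
        object.__setattr__(self, "initial_state", x0)
        if x0.size != self.state_dim:
            raise ValueError(
                f"initial_state has length {x0.size}, expected {self.state_dim}"
            )


@dataclass(frozen=True)
class ExperimentDesign:
    """One experiment: fixed controls, a sampling grid and observed states.

    ``observed_states`` uses 1-based state indices.
    """

    experiment_id: int
    controls: Mapping[str, float]
    sample_times: np.ndarray
    observed_states: tuple[int, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.sample_times, dtype=float)
        object.__setattr__(self, "sample_times", times)
        object.__setattr__(self, "observed_states", tuple(self.observed_states))
        if times.ndim != 1 or times.size == 0:
            raise ValueError("sample_times must be a nonempty 1-D vector")
        if times[0] < 0 or (np.diff(times) <= 0).any():
            raise ValueError("sample_times must be strictly increasing and start at >= 0")
        if any(s < 1 for s in self.observed_states):
            raise ValueError("observed_states are 1-based state indices")


# --------------------------------------------------------------------------
# Right-hand sides
# --------------------------------------------------------------------------

def alpha_pinene_rhs(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """First-order reaction network for the thermal isomerization of α-pinene.

    dy1/dt = −(p1+p2)·y1
    dy2/dt = p1·y1
    dy3/dt = p2·y1 − (p3+p4)·y3 + p5·y5
    dy4/dt = p3·y3
    dy5/dt = p4·y3 − p5·y5

    The network is closed, so the components sum to zero (total mass is
    conserved).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != (5,) or p.shape != (5,):
        raise ValueError("alpha_pinene_rhs expects 5-vectors y and p")
    a = p[0] * y[0]
    b = p[1] * y[0]
    c = p[2] * y[2]
    d = p[3] * y[2]
    e = p[4] * y[4]
    return np.array([-a - b, a, b - c - d + e, c, d - e])


def three_step_rhs(x: np.ndarray, theta: np.ndarray, S: float, P: float) -> np.ndarray:
    """Three-step pathway: 8 states (G1,G2,G3,E1,E2,E3,M1,M2), 36 parameters.

    Gene transcription is repressed by the product P (Hill coefficient ni)
    and activated by an upstream species X_i (S for G1, M1 for G2, M2 for
    G3; Hill coefficient na):

        dGi/dt = Vi / (1 + (P/Ki_i)^{ni_i} + (Ka_i/X_i)^{na_i}) − k_i·Gi

    Enzymes follow saturable production from their transcript:

        dE_i/dt = V_{3+i}·G_i/(K_{3+i}+G_i) − k_{3+i}·E_i

    and the metabolites are driven by reversible Michaelis–Menten fluxes

        flux(E, A, B; kcat, KmA, KmB) = kcat·E·(A−B)/KmA / (1 + A/KmA + B/KmB)

    from S→M1→M2→P.

    Raises :class:`ValueError` (naming the offending Hill term) when a
    non-positive concentration would be raised to a non-integer power.
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if x.shape != (8,):
        raise ValueError("three_step_rhs expects an 8-vector state")
    if theta.shape != (36,):
        raise ValueError("three_step_rhs expects 36 parameters")
    (G1, G2, G3, E1, E2, E3, M1, M2) = x
    (V1, Ki1, ni1, Ka1, na1, k1,
     V2, Ki2, ni2, Ka2, na2, k2,
     V3, Ki3, ni3, Ka3, na3, k3,
     V4, K4, k4, V5, K5, k5, V6, K6, k6,
     kcat1, Km1, Km2, kcat2, Km3, Km4, kcat3, Km5, Km6) = theta

    def hill(base: float, expo: float, label: str) -> float:
        if base < 0 or (base == 0 and expo < 0):
            raise ValueError(f"non-positive base in Hill term {label}: base={base}")
        if base == 0:
            return 0.0
        return base ** expo

    dG1 = V1 / (1.0 + hill(P / Ki1, ni1, "(P/Ki1)^ni1")
                + hill(Ka1 / S, na1, "(Ka1/S)^na1")) - k1 * G1
    dG2 = V2 / (1.0 + hill(P / Ki2, ni2, "(P/Ki2)^ni2")
                + hill(Ka2 / M1, na2, "(Ka2/M1)^na2")) - k2 * G2
    dG3 = V3 / (1.0 + hill(P / Ki3, ni3, "(P/Ki3)^ni3")
                + hill(Ka3 / M2, na3, "(Ka3/M2)^na3")) - k3 * G3
    dE1 = V4 * G1 / (K4 + G1) - k4 * E1
    dE2 = V5 * G2 / (K5 + G2) - k5 * E2
    dE3 = V6 * G3 / (K6 + G3) - k6 * E3
    flux1 = kcat1 * E1 * (S - M1) / Km1 / (1.0 + S / Km1 + M1 / Km2)
    flux2 = kcat2 * E2 * (M1 - M2) / Km3 / (1.0 + M1 / Km3 + M2 / Km4)
    flux3 = kcat3 * E3 * (M2 - P) / Km5 / (1.0 + M2 / Km5 + P / Km6)
    dM1 = flux1 - flux2
    dM2 = flux2 - flux3
    return np.array([dG1, dG2, dG3, dE1, dE2, dE3, dM1, dM2])


# --------------------------------------------------------------------------
# Registry, nominal parameters, experiment grids
# --------------------------------------------------------------------------

def _alpha_pinene_model_rhs(x, p, controls, t):
    return alpha_pinene_rhs(x, p)


def _three_step_model_rhs(x, theta, controls, t):
    return three_step_rhs(x, theta, controls["S"], controls["P"])


ALPHA_PINENE = OdeModel(
    name="alpha_pinene",
    state_dim=5,
    rhs=_alpha_pinene_model_rhs,
    initial_state=CASE1_X0,
)

THREE_STEP = OdeModel(
    name="three_step",
    state_dim=8,
    rhs=_three_step_model_rhs,
    initial_state=CASE2_X0,
    controls={"S": CASE2_S_LEVELS[0], "P": CASE2_P_LEVELS[0]},
)

#: Models addressable by name from configs and the CLI.  User-defined models
#: may be registered here; they must follow the OdeModel.rhs signature.
MODEL_REGISTRY: dict[str, OdeModel] = {
    "alpha_pinene": ALPHA_PINENE,
    "three_step": THREE_STEP,
}


def get_model(name: str) -> OdeModel:
    """Look a model up by registry name."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


def _check_case(case: int) -> None:
    if case not in (1, 2):
        raise ValueError(f"case must be 1 or 2, got {case!r}")


def default_bounds(case: int) -> tuple[np.ndarray, np.ndarray]:
    """Default search box (θL, θU) for a benchmark case."""
    _check_case(case)
    lo, hi = CASE1_BOUNDS if case == 1 else CASE2_BOUNDS
    return lo.copy(), hi.copy()


def nominal_parameters(case: int) -> ParameterVector:
    """True parameter values used to generate pseudo-experimental data."""
    _check_case(case)
    values = CASE1_NOMINAL if case == 1 else CASE2_NOMINAL
    lo, hi = default_bounds(case)
    return ParameterVector(values.copy(), lo, hi)


def experiment_grid(
    case: int, sample_times: Sequence[float] | None = None
) -> list[ExperimentDesign]:
    """Experiment designs for a benchmark case.

    Case 1 is a single experiment with no controls; case 2 is the 4×4
    Cartesian product of the S and P levels (S-major, then P), i.e. 16
    pseudo-experiments observing all 8 states.
    """
    _check_case(case)
    if case == 1:
        times = CASE1_SAMPLE_TIMES if sample_times is None else np.asarray(sample_times)
        return [
            ExperimentDesign(
                experiment_id=0,
                controls={},
                sample_times=times,
                observed_states=tuple(range(1, 6)),
            )
        ]
    times = CASE2_SAMPLE_TIMES if sample_times is None else np.asarray(sample_times)
    designs = []
    eid = 0
    for S in CASE2_S_LEVELS:
        for P in CASE2_P_LEVELS:
            designs.append(
                ExperimentDesign(
                    experiment_id=eid,
                    controls={"S": S, "P": P},
                    sample_times=times,
                    observed_states=tuple(range(1, 9)),
                )
            )
            eid += 1
    return designs
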