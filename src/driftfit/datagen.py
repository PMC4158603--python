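"""Pseudo-experimental data: nominal-model simulation plus white noise.

The "measurements" the optimizers fit are not laboratory data — they are the
model's own output at the nominal (true) parameters, optionally corrupted by
additive homoscedastic Gaussian noise z' = z + σ·ε with ε ~ N(0,1) i.i.d.
per cell (σ = 0.01 in the benchmark protocol, identical for every variable
and time point regardless of scale).

Noise draws are taken from a single seeded generator in fixed cell order
(experiment-major, time-major, variable-minor) so a dataset is reproducible
from (case, σ, seed, integrator settings) alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as _models
from .forward import simulate_all
from .models import ExperimentDesign, nominal_parameters

__all__ = ["Dataset", "generate_noise_free", "add_noise", "write_csv", "read_csv"]


@dataclass(frozen=True)
class Dataset:
    """Observed values on a common time grid for a list of experiments.

    ``values`` has shape (n_experiments, n_times, n_observed); observed-state
    indices are 1-based.
    """

    values: np.ndarray
    times: np.ndarray
    experiment_ids: tuple[int, ...]
    observed_states: tuple[int, ...]
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "experiment_ids", tuple(self.experiment_ids))
        object.__setattr__(self, "observed_states", tuple(self.observed_states))
        expected = (len(self.experiment_ids), times.size, len(self.observed_states))
        if values.shape != expected:
            raise ValueError(f"values shape {values.shape} != {expected}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_noise_free(
    case: int,
    designs: list[ExperimentDesign] | None = None,
    substeps: int = 20,
) -> Dataset:
    """Simulate the nominal model over the case's experiment designs.

    Deterministic; regenerating with identical settings gives a bit-identical
    dataset, so the weighted least-squares objective evaluated at the nominal
    parameters on this dataset is exactly zero.
    """
    if designs is None:
        designs = _models.experiment_grid(case)
    theta = nominal_parameters(case)
    model = _models.get_model(_models.CASE_NAMES[case])
    trajectories = simulate_all(model, theta, designs, substeps)
    times = designs[0].sample_times
    observed = designs[0].observed_states
    for d in designs:
        if d.sample_times.shape != times.shape or not np.array_equal(d.sample_times, times):
            raise ValueError("all designs must share one sample-time grid")
        if d.observed_states != observed:
            raise ValueError("all designs must observe the same states")
    cols = [s - 1 for s in observed]
    values = np.stack([t.states[:, cols] for t in trajectories])
    if any(t.diverged for t in trajectories):
        raise RuntimeError("nominal-model simulation diverged")
    return Dataset(
        values=values,
        times=times,
        experiment_ids=tuple(d.experiment_id for d in designs),
        observed_states=observed,
    )


def add_noise(data: Dataset, sigma: float, seed: int) -> Dataset:
    """Additive white Gaussian noise, z' = z + σ·ε, seeded and reproducible.

    The input dataset is not modified.  σ = 0 returns an identical copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return replace(data, noise_sigma=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    # C-order standard_normal over (experiment, time, variable) realizes the
    # documented experiment-major, time-major, variable-minor draw order.
    noisy = data.values + sigma * rng.standard_normal(data.values.shape)
    return replace(data, values=noisy, noise_sigma=float(sigma), seed=seed)


# --------------------------------------------------------------------------
# CSV round trip (long format) with a JSON metadata sidecar
# --------------------------------------------------------------------------

def _to_frame(data: Dataset) -> pd.DataFrame:
    n_exp, n_t, n_v = data.values.shape
    eid = np.repeat(data.experiment_ids, n_t * n_v)
    time = np.tile(np.repeat(data.times, n_v), n_exp)
    var = np.tile(data.observed_states, n_exp * n_t)
    return pd.DataFrame(
        {
            "experiment_id": eid,
            "time": time,
            "variable": var,
            "value": data.values.ravel(),
        }
    )


def write_csv(data: Dataset, path: str | Path, metadata: dict | None = None) -> None:
    """Long-format CSV (experiment_id, time, variable, value) + JSON sidecar."""
    path = Path(path)
    _to_frame(data).to_csv(path, index=False)
    meta = {
        "noise_sigma": data.noise_sigma,
        "seed": data.seed,
        "experiment_ids": list(data.experiment_ids),
        "observed_states": list(data.observed_states),
    }
    if metadata:
        meta.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_csv(path: str | Path) -> Dataset:
    """Inverse of :func:`write_csv`."""
    path = Path(path)
    frame = pd.read_csv(path)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    eids = sorted(frame["experiment_id"].unique())
    times = np.sort(frame["time"].unique())
    variables = sorted(frame["variable"].unique())
    values = np.empty((len(eids), times.size, len(variables)))
    pivot = frame.set_index(["experiment_id", "time", "variable"])["value"]
    for i, eid in enumerate(eids):
        for j, t in enumerate(times):
            for k, v in enumerate(variables):
                values[i, j, k] = pivot.loc[(eid, t, v)]
    return Dataset(
        values=values,
        times=times,
        experiment_ids=tuple(int(e) for e in eids),
        observed_states=tuple(int(v) for v in variables),
        noise_sigma=float(meta.get("noise_sigma", 0.0)),
        seed=meta.get("seed"),
    )
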