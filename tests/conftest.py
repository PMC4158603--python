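"""Shared fixtures: benchmark problems (session-scoped — building a problem
compiles the integration kernels) and a scripted RNG for exact-trace tests."""

from __future__ import annotations

import numpy as np
import pytest

from driftfit import build_problem, nominal_parameters


class ScriptedRng:
    """Replays a pre-recorded stream through the Generator.random interface."""

    def __init__(self, values):
        self._values = list(values)

    def random(self, size=None):
        if size is None:
            return self._values.pop(0)
        out = np.array([self._values.pop(0) for _ in range(size)])
        return out


@pytest.fixture(scope="session")
def case1_problem():
    return build_problem(1)


@pytest.fixture(scope="session")
def case2_problem():
    return build_problem(2)


@pytest.fixture(scope="session")
def case1_nominal():
    return nominal_parameters(1)


@pytest.fixture(scope="session")
def case2_nominal():
    return nominal_parameters(2)
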