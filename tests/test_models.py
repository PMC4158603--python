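"""Benchmark model definitions: right-hand sides, nominal values, designs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftfit import (
    ParameterVector,
    alpha_pinene_rhs,
    default_bounds,
    experiment_grid,
    get_model,
    nominal_parameters,
    three_step_rhs,
)
from driftfit.models import CASE2_NOMINAL, CASE2_PARAM_NAMES


class TestAlphaPineneRhs:
    def test_nominal_derivatives_from_pure_reactant(self):
        y = np.array([100.0, 0, 0, 0, 0])
        p = nominal_parameters(1).values
        dy = alpha_pinene_rhs(y, p)
        # hand-evaluated: dy1 = -(p1+p2)*100, dy2 = p1*100, dy4 = p3*y3 = 0
        assert dy[0] == pytest.approx(-8.89e-3, rel=1e-12)
        assert dy[1] == pytest.approx(5.93e-3, rel=1e-12)
        assert dy[3] == 0.0

    def test_zero_rates_give_zero_derivative(self):
        dy = alpha_pinene_rhs(np.array([3.0, 1, 4, 1, 5]), np.zeros(5))
        assert np.all(dy == 0)

    @given(
        y=st.lists(st.floats(0, 100), min_size=5, max_size=5),
        p=st.lists(st.floats(0, 1e-3), min_size=5, max_size=5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_conservation(self, y, p):
        """The network is closed: derivative components cancel (to rounding)."""
        dy = alpha_pinene_rhs(np.array(y), np.array(p))
        scale = np.abs(dy).max() or 1.0
        assert abs(dy.sum()) <= 1e-12 * scale

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            alpha_pinene_rhs(np.zeros(4), np.zeros(5))


class TestThreeStepRhs:
    def test_zero_production_and_decay_is_stationary(self):
        theta = CASE2_NOMINAL.copy()
        # zero every V, k and kcat; leave the K/Ki/Ka/Hill parameters alone
        for i, name in enumerate(CASE2_PARAM_NAMES):
            if name[0] in ("V", "k"):
                theta[i] = 0.0
        dx = three_step_rhs(np.full(8, 0.3), theta, S=0.1, P=0.05)
        assert np.all(dx == 0)

    def test_g1_production_at_zero_transcript(self):
        x = np.zeros(8)
        x[6] = x[7] = 0.2  # keep the other Hill terms defined
        dx = three_step_rhs(x, CASE2_NOMINAL, S=0.1, P=0.05)
        # dG1 = 1/(1 + 0.05^2 + (1/0.1)^2), hand-evaluated
        assert dx[0] == pytest.approx(1.0 / 101.0025, rel=1e-12)

    def test_equal_metabolites_zero_middle_flux(self):
        """With M1 = M2 the M1→M2 flux vanishes; dM1 then only carries the
        upstream flux and dM2 only the downstream one."""
        x = np.array([0.1, 0.1, 0.1, 0.5, 0.7, 0.1, 0.3, 0.3])
        theta = CASE2_NOMINAL
        dx = three_step_rhs(x, theta, S=0.3, P=0.05)
        # flux2 = 0, so dM1 = flux1 and dM2 = -flux3; recompute both directly
        flux1 = 1.0 * 0.5 * (0.3 - 0.3) / 1.0 / (1 + 0.3 + 0.3)
        flux3 = 1.0 * 0.1 * (0.3 - 0.05) / 1.0 / (1 + 0.3 + 0.05)
        assert dx[6] == pytest.approx(flux1, abs=1e-15)
        assert dx[7] == pytest.approx(-flux3, rel=1e-12)

    def test_negative_concentration_domain_error(self):
        x = np.full(8, 0.1)
        x[6] = -0.2  # M1 < 0 under a fractional Hill exponent
        theta = CASE2_NOMINAL.copy()
        theta[10] = 2.5
        with pytest.raises(ValueError, match="Ka2/M1"):
            three_step_rhs(x, theta, S=0.1, P=0.05)

    def test_finite_at_nominal_on_every_grid_point(self):
        for d in experiment_grid(2):
            dx = three_step_rhs(
                np.full(8, 0.1), CASE2_NOMINAL, d.controls["S"], d.controls["P"]
            )
            assert np.isfinite(dx).all()


class TestNominalParameters:
    def test_case1_values(self):
        p = nominal_parameters(1)
        assert len(p) == 5
        assert p.values[0] == 5.93e-5
        assert p.values[3] == 27.5e-5

    def test_case2_values(self):
        theta = nominal_parameters(2)
        assert len(theta) == 36
        assert theta.values[2] == 2.0   # ni1
        assert theta.values[18] == 0.1  # V4
        assert theta.values[27] == 1.0  # kcat1

    def test_nominal_within_default_bounds(self):
        for case in (1, 2):
            lo, hi = default_bounds(case)
            v = nominal_parameters(case).values
            assert np.all(v >= lo) and np.all(v <= hi)

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError):
            nominal_parameters(3)


class TestExperimentGrid:
    def test_case1_single_experiment_without_controls(self):
        designs = experiment_grid(1)
        assert len(designs) == 1
        assert dict(designs[0].controls) == {}

    def test_case2_full_factorial(self):
        designs = experiment_grid(2)
        assert len(designs) == 16
        pairs = {(d.controls["S"], d.controls["P"]) for d in designs}
        assert (2.1544, 1.0) in pairs
        assert len(pairs) == 16
        # deterministic S-major ordering
        assert designs[0].controls == {"S": 0.1, "P": 0.05}
        assert designs[1].controls == {"S": 0.1, "P": 0.13572}


class TestParameterVector:
    def test_bounds_violation_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector(np.array([2.0]), np.array([0.0]), np.array([1.0]))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector(np.array([0.5]), np.array([1.0]), np.array([0.0]))

    def test_clip_and_replace(self):
        pv = nominal_parameters(1)
        clipped = pv.clip(np.full(5, 1.0))
        assert np.all(clipped == pv.upper)
        assert np.all(pv.replace(clipped).values == pv.upper)

    def test_model_registry(self):
        assert get_model("alpha_pinene").state_dim == 5
        assert get_model("three_step").state_dim == 8
        with pytest.raises(KeyError):
            get_model("nope")
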