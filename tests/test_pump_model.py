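"""Unit and property tests for the piecewise pump model and its integrator."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ionloop.pump_model import (
    PumpParams,
    PumpPlant,
    PumpState,
    Region,
    classify_region,
    pump_rhs,
    step_pump,
)


class TestRegionDispatch:
    @pytest.mark.parametrize("u_factory,expected", [
        (lambda p: p.epsilon + 1.0, Region.HIGH_POS),
        (lambda p: p.epsilon, Region.LOW_POS),       # closed at epsilon
        (lambda p: p.epsilon / 2, Region.LOW_POS),
        (lambda p: 0.0, Region.LOW_NEG),             # closed at 0
        (lambda p: -p.zeta / 2, Region.LOW_NEG),
        (lambda p: -p.zeta, Region.LOW_NEG),         # closed at -zeta
        (lambda p: -2 * p.zeta, Region.HIGH_NEG),
    ])
    def test_boundary_assignment(self, simple_params, u_factory, expected):
        assert classify_region(u_factory(simple_params), simple_params) is expected

    def test_partition_of_real_line(self, simple_params, rng):
        """10^5 random voltages: the four inequalities agree with dispatch
        and select exactly one region each."""
        p = simple_params
        us = rng.uniform(-5, 5, size=100_000)
        for u in us:
            flags = [u > p.epsilon,
                     p.epsilon >= u > 0,
                     0 >= u >= -p.zeta,
                     -p.zeta > u]
            assert sum(flags) == 1
            chosen = [Region.HIGH_POS, Region.LOW_POS,
                      Region.LOW_NEG, Region.HIGH_NEG][flags.index(True)]
            assert classify_region(u, p) is chosen


class TestRHS:
    def test_equilibrium_at_equal_concentrations_no_leak(self):
        p = PumpParams(D=0.5, c1=1, c2=1, cc1=1, cc2=1, d1=1, d2=1,
                       dd1=1, dd2=1, g=0.0, epsilon=0.5, zeta=0.5)
        assert pump_rhs(PumpState(3.0, 3.0), 0.0, p) == (0.0, 0.0)

    def test_zero_voltage_is_pure_diffusion_and_leak(self, simple_params):
        a, b = 2.0, 7.0
        dx1, dx2 = pump_rhs(PumpState(a, b), 0.0, simple_params)
        D, g = simple_params.D, simple_params.g
        assert dx1 == pytest.approx(D * (b - a) - g * a, abs=1e-15)
        assert dx2 == pytest.approx(D * (a - b), abs=1e-15)

    def test_hill_term_half_maximal_in_high_pos(self, simple_params):
        """With x2 = d1 the strongly-positive actuation contributes u*c1/2."""
        p = simple_params
        u = p.epsilon + 1.0
        x1 = 4.0
        base = pump_rhs(PumpState(x1, p.d1), 0.0, p)
        act = pump_rhs(PumpState(x1, p.d1), u, p)
        assert act[0] - base[0] == pytest.approx(u * p.c1 / 2, rel=1e-12)

    @given(x1=st.floats(0, 100), x2=st.floats(0, 100),
           u=st.floats(-3, 3))
    @settings(max_examples=200, deadline=None)
    def test_diffusion_conserves_mass_without_leak_or_drive(self, x1, x2, u):
        p = PumpParams(D=0.3, c1=1, c2=1, cc1=1, cc2=1, d1=5, d2=5,
                       dd1=5, dd2=5, g=0.0, epsilon=0.5, zeta=0.5)
        dx1, dx2 = pump_rhs(PumpState(x1, x2), 0.0, p)
        assert abs(dx1 + dx2) < 1e-12

    def test_high_neg_mixed_denominators_as_written(self):
        """The strongly-negative region uses d1 in the x1 equation and d2 in
        the x2 equation unless the symmetric switch is set."""
        p = PumpParams(D=0.0, c1=1, c2=1, cc1=1, cc2=1, d1=2.0, d2=6.0,
                       dd1=1, dd2=1, g=0.0, epsilon=0.5, zeta=0.5)
        u, x1 = -2.0, 3.0
        dx1, dx2 = pump_rhs(PumpState(x1, 0.0), u, p)
        assert dx1 == pytest.approx(u * p.c2 * x1 / (p.d1 + x1))
        assert dx2 == pytest.approx(u * p.c2 * x1 / (p.d2 + x1))
        sym = replace(p, symmetric_denominators=True)
        dx1s, _ = pump_rhs(PumpState(x1, 0.0), u, sym)
        assert dx1s == pytest.approx(u * p.c2 * x1 / (p.d2 + x1))

    def test_actuation_same_sign_in_both_compartments_as_written(self, simple_params):
        """Positive drive raises both x1 and x2 rates (non-conservative as
        written); the conservative switch flips the x2 contribution."""
        p = simple_params
        u = p.epsilon + 1.0
        s = PumpState(1.0, 5.0)
        base = pump_rhs(s, 0.0, p)
        drv = pump_rhs(s, u, p)
        act1, act2 = drv[0] - base[0], drv[1] - base[1]
        assert act1 == pytest.approx(act2, rel=1e-12)
        cons = replace(p, conservative_actuation=True)
        drv_c = pump_rhs(s, u, cons)
        assert drv_c[1] - base[1] == pytest.approx(-act2, rel=1e-12)


class TestIntegrator:
    def test_equilibrium_state_is_fixed_point(self):
        p = PumpParams(D=0.5, c1=1, c2=1, cc1=1, cc2=1, d1=1, d2=1,
                       dd1=1, dd2=1, g=0.0, epsilon=0.5, zeta=0.5)
        s = step_pump(PumpState(3.0, 3.0), 0.0, dt=1.0, params=p, substeps=10)
        assert s.x1 == pytest.approx(3.0, abs=1e-14)
        assert s.x2 == pytest.approx(3.0, abs=1e-14)

    def test_agrees_with_euler_at_tiny_step(self, simple_params):
        """One RK4 step at dt=1e-6 matches explicit Euler to O(dt^2)."""
        s0 = PumpState(2.0, 9.0)
        u, dt = 1.2, 1e-6
        rk = step_pump(s0, u, dt, simple_params)
        k = pump_rhs(s0, u, simple_params)
        assert rk.x1 == pytest.approx(s0.x1 + dt * k[0], abs=1e-11)
        assert rk.x2 == pytest.approx(s0.x2 + dt * k[1], abs=1e-11)

    def test_exponential_decay_limit(self):
        """With D=0, u=0 the target decays as x1(0)*exp(-g t) and the
        reservoir stays put."""
        g = 0.2
        p = PumpParams(D=0.0, c1=1, c2=1, cc1=1, cc2=1, d1=1, d2=1,
                       dd1=1, dd2=1, g=g, epsilon=0.5, zeta=0.5)
        s = PumpState(5.0, 4.0)
        t = 0.0
        for _ in range(500):
            s = step_pump(s, 0.0, dt=0.01, params=p)
            t += 0.01
        assert s.x1 == pytest.approx(5.0 * math.exp(-g * t), rel=1e-6)
        assert s.x2 == 4.0

    def test_non_finite_input_raises(self, simple_params):
        with pytest.raises(FloatingPointError):
            step_pump(PumpState(1.0, 1.0), math.nan, 0.1, simple_params)

    def test_negative_excursions_clipped(self, simple_params):
        """Strong negative drive cannot push concentrations below zero."""
        s = PumpState(0.5, 0.5)
        for _ in range(50):
            s = step_pump(s, -3.0, 1.0, simple_params, substeps=10)
        assert s.x1 >= 0 and s.x2 >= 0

    def test_invalid_dt_rejected(self, simple_params):
        with pytest.raises(ValueError):
            step_pump(PumpState(1, 1), 0.0, 0.0, simple_params)


class TestPlantContract:
    def test_apply_advances_and_returns_x1(self, insilico_plant):
        y0 = insilico_plant.y
        y1 = insilico_plant.apply(1.0)
        assert y1 == insilico_plant.state.x1
        assert y1 > y0  # positive drive fills the target from empty

    def test_reset_restores_initial_state(self, insilico_plant):
        initial = insilico_plant.state
        insilico_plant.apply(1.0)
        insilico_plant.reset()
        assert insilico_plant.state == initial

    def test_scaled_plant_trajectories_scale_linearly(self, insilico_plant):
        """Rescaling rates, half-maxima and state by a factor rescales the
        whole trajectory by that factor (unit-change invariance)."""
        factor = 70.0
        big = insilico_plant.scaled(factor)
        for u in (0.5, 1.0, 1.4, 0.8):
            y_small = insilico_plant.apply(u)
            y_big = big.apply(u)
            assert y_big == pytest.approx(factor * y_small, rel=1e-10)


class TestParamValidation:
    @pytest.mark.parametrize("field,value", [
        ("D", -0.1), ("g", -1.0), ("epsilon", 0.0), ("zeta", -0.5),
    ])
    def test_invalid_parameters_rejected(self, simple_params, field, value):
        with pytest.raises(ValueError):
            replace(simple_params, **{field: value})

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            PumpState(-1.0, 0.0)
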