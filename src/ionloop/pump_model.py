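"""Piecewise nonlinear ODE model of the bioelectronic ion pump.

The pump moves a charged drug electrophoretically from a reservoir
(concentration ``x2``) through a hydrogel capillary into a target region
(concentration ``x1``) under an applied voltage ``u``.  The dynamics are a
two-compartment model with Fickian exchange between the compartments, a
leakage term draining the target, and a voltage-driven actuation term whose
strength follows a Hill saturation in the donor concentration.  The applied
voltage axis is split into four regions — strongly positive, weakly
positive, weakly negative, strongly negative — separated by thresholds
``epsilon`` (positive side) and ``-zeta`` (negative side), each region
carrying its own actuation rate and half-maximal constant.

The model as written is deliberately non-conservative: the actuation term
enters both compartment derivatives with the same sign, and the strongly
negative region uses different half-maximal constants in its two equations.
Both behaviours can be overridden via :class:`PumpParams` switches
(``conservative_actuation``, ``symmetric_denominators``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Region",
    "PumpParams",
    "PumpState",
    "PumpPlant",
    "classify_region",
    "pump_rhs",
    "step_pump",
]


class Region(enum.Enum):
    """Voltage region of the piecewise pump model."""

    HIGH_POS = "high_pos"  # u > epsilon
    LOW_POS = "low_pos"    # epsilon >= u > 0
    LOW_NEG = "low_neg"    # 0 >= u >= -zeta
    HIGH_NEG = "high_neg"  # u < -zeta


@dataclass(frozen=True)
class PumpParams:
    """Parameters of the piecewise pump model.

    Rates ``c1, c2`` (resp. ``cc1, cc2``) are the maximum actuation rates in
    the strongly (resp. weakly) biased regions, in concentration/(V*s).
    ``d1, d2`` / ``dd1, dd2`` are the Hill half-maximal constants pairing
    with them (concentration units).  ``D`` is the diffusion exchange rate
    and ``g`` the target-side leakage rate, both 1/s.  ``epsilon`` and
    ``zeta`` are the positive-side threshold and negative-side threshold
    magnitude (V).
    """

    D: float
    c1: float
    c2: float
    cc1: float
    cc2: float
    d1: float
    d2: float
    dd1: float
    dd2: float
    g: float
    epsilon: float
    zeta: float
    conservative_actuation: bool = False
    symmetric_denominators: bool = False

    def __post_init__(self) -> None:
        for name in ("D", "c1", "c2", "cc1", "cc2", "d1", "d2", "dd1", "dd2", "g"):
            if getattr(self, name) < 0:
                raise ValueError(f"PumpParams.{name} must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("PumpParams.epsilon must be > 0")
        if self.zeta <= 0:
            raise ValueError("PumpParams.zeta must be > 0")


@dataclass(frozen=True)
class PumpState:
    """Compartment concentrations: ``x1`` target area, ``x2`` reservoir+bridge."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("concentrations must be non-negative")


def classify_region(u: float, params: PumpParams) -> Region:
    """Return the voltage region of ``u``.

    Boundaries follow the closed/open pattern of the model definition:
    ``u = epsilon`` belongs to LOW_POS, ``u = 0`` and ``u = -zeta`` to
    LOW_NEG.
    """
    if u > params.epsilon:
        return Region.HIGH_POS
    if u > 0:
        return Region.LOW_POS
    if u >= -params.zeta:
        return Region.LOW_NEG
    return Region.HIGH_NEG


def pump_rhs(state: PumpState, u: float, params: PumpParams) -> tuple[float, float]:
    """Time derivatives ``(dx1/dt, dx2/dt)`` for the current voltage region."""
    x1, x2 = state.x1, state.x2
    diff1 = params.D * (x2 - x1)
    diff2 = params.D * (x1 - x2)
    region = classify_region(u, params)

    if region is Region.HIGH_POS:
        act1 = act2 = u * params.c1 * x2 / (params.d1 + x2)
    elif region is Region.LOW_POS:
        act1 = act2 = u * params.cc1 * x2 / (params.dd1 + x2)
    elif region is Region.LOW_NEG:
        act1 = act2 = u * params.cc2 * x1 / (params.dd2 + x1)
    else:  # HIGH_NEG: the two equations use different half-maximal constants
        den1 = params.d2 if params.symmetric_denominators else params.d1
        act1 = u * params.c2 * x1 / (den1 + x1)
        act2 = u * params.c2 * x1 / (params.d2 + x1)

    if params.conservative_actuation:
        act2 = -act2

    return diff1 + act1 - params.g * x1, diff2 + act2


def step_pump(state: PumpState, u: float, dt: float, params: PumpParams,
              substeps: int = 1) -> PumpState:
    """Advance the pump state by ``dt`` with the voltage held constant.

    Classical fixed-step RK4, optionally subdivided into ``substeps`` equal
    internal steps; concentrations are clipped at zero after each internal
    step because large negative voltages can otherwise drive the model into
    unphysical negative concentrations.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if not (math.isfinite(state.x1) and math.isfinite(state.x2) and math.isfinite(u)):
        raise FloatingPointError("non-finite state or control in step_pump")

    h = dt / substeps
    x1, x2 = state.x1, state.x2
    for _ in range(substeps):
        s0 = PumpState(max(x1, 0.0), max(x2, 0.0))
        k1 = pump_rhs(s0, u, params)
        k2 = pump_rhs(_offset(s0, k1, h / 2), u, params)
        k3 = pump_rhs(_offset(s0, k2, h / 2), u, params)
        k4 = pump_rhs(_offset(s0, k3, h), u, params)
        x1 = s0.x1 + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        x2 = s0.x2 + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        if not (math.isfinite(x1) and math.isfinite(x2)):
            raise FloatingPointError("pump integration diverged (non-finite state)")
        x1, x2 = max(x1, 0.0), max(x2, 0.0)
    return PumpState(x1, x2)


def _offset(s: PumpState, k: tuple[float, float], h: float) -> PumpState:
    # intermediate RK4 stages may transiently go negative; clip for the Hill terms
    return PumpState(max(s.x1 + h * k[0], 0.0), max(s.x2 + h * k[1], 0.0))


@dataclass
class PumpPlant:
    """Simulated plant satisfying the shared plant contract ``apply(u) -> y``.

    ``apply`` holds the saturated voltage constant for one sampling period
    ``T`` (zero-order hold), advances the ODE by RK4 sub-stepping, and
    returns the measured output, which for this plant is the target-side
    concentration ``x1``.
    """

    params: PumpParams
    state: PumpState
    T: float = 1.0
    substeps: int = 10
    _initial: PumpState = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._initial = self.state

    @property
    def y(self) -> float:
        """Current measured output (target-side concentration)."""
        return self.state.x1

    def apply(self, u_sat: float) -> float:
        self.state = step_pump(self.state, u_sat, self.T, self.params,
                               substeps=self.substeps)
        return self.state.x1

    def reset(self) -> None:
        self.state = self._initial

    def scaled(self, factor: float) -> "PumpPlant":
        """A copy with the concentration axis rescaled by ``factor``.

        Multiplying the actuation rates, half-maximal constants and initial
        state by the same factor rescales every trajectory linearly, which
        is how a preset expressed in one output unit is reused at another
        operating point (e.g. fluorescence-scale vs nA-scale).
        """
        p = self.params
        params = replace(p, c1=p.c1 * factor, c2=p.c2 * factor,
                         cc1=p.cc1 * factor, cc2=p.cc2 * factor,
                         d1=p.d1 * factor, d2=p.d2 * factor,
                         dd1=p.dd1 * factor, dd2=p.dd2 * factor)
        state = PumpState(self.state.x1 * factor, self.state.x2 * factor)
        return PumpPlant(params=params, state=state, T=self.T, substeps=self.substeps)
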