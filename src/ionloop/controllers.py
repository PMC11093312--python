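"""Saturation-aware sliding-mode controller and hard-clipped PID baseline.

The sliding-mode controller (SMC) tracks a reference by driving the error
onto the manifold ``s = K*e + de/dt`` and holding it there with a switching
term.  Two features distinguish it from a textbook SMC:

* **Chattering mitigation by rate integration.**  The switching (bang-bang)
  signal is emitted as an *artificial control rate* ``nu = mu*rho*sign(Q*s)``
  and integrated with the trapezoidal rule to obtain the raw control ``u``,
  so the applied signal is continuous rather than discontinuous.

* **Structural saturation handling.**  The applied voltage is
  ``u_sat = A_max*sin(u)``: whatever the integrator state, the emitted
  command can never leave ``[-A_max, +A_max]``.  The factor
  ``cos(u_prev)`` inside the sign argument is the gradient of this
  actuating nonlinearity — when the integrator passes a peak of the sine,
  the effective sign of the control authority flips and the switching term
  flips with it.

A heuristic gain switch selects ``(K, rho) = (kappa1, rho1)`` when the
error is positive and ``(kappa2, rho2)`` otherwise, allowing asymmetric
response rates in the two directions.

The PID baseline is a discrete positional PID whose output is manually
clipped to ``[-A_max, +A_max]`` after computation, with no anti-windup:
the internal integral keeps accumulating while the emitted command sits at
the bound, mirroring a "hard limit" applied outside the control law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SMCConfig",
    "SMCState",
    "PIDConfig",
    "SlidingModeController",
    "PIDController",
    "tracking_error",
    "select_gains",
    "sliding_surface",
    "artificial_control",
    "integrate_control",
    "saturate",
    "smc_step",
    "pid_step",
]


@dataclass(frozen=True)
class SMCConfig:
    """Sliding-mode controller gains and structure.

    ``kappa1/kappa2`` are the candidate manifold gains and ``rho1/rho2``
    the candidate switching-rate magnitudes, selected per-sample by the
    sign of the error.  ``mu`` is the experimentally determined sign of the
    plant input gain (-1 for a monotonically increasing response).
    ``A_max`` is the voltage amplitude limit (V), ``T`` the sampling time
    (s), ``u_init`` the initial raw control and ``n`` the number of samples
    in an experiment.
    """

    kappa1: float
    kappa2: float
    rho1: float
    rho2: float
    A_max: float
    T: float = 1.0
    mu: int = -1
    u_init: float = 0.0
    n: int = 1200

    def __post_init__(self) -> None:
        for name in ("kappa1", "kappa2", "rho1", "rho2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SMCConfig.{name} must be > 0")
        if self.A_max <= 0:
            raise ValueError("SMCConfig.A_max must be > 0")
        if self.T <= 0:
            raise ValueError("SMCConfig.T must be > 0")
        if self.mu not in (-1, 1):
            raise ValueError("SMCConfig.mu must be -1 or +1")


@dataclass
class SMCState:
    """Per-step controller memory: previous raw control, rate and error."""

    u_prev: float
    nu_prev: float
    e_prev: float
    step_index: int = 2


@dataclass(frozen=True)
class PIDConfig:
    """Discrete PID gains with an external hard clip at ``+-A_max``."""

    kp: float
    ki: float
    kd: float
    A_max: float
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.A_max <= 0:
            raise ValueError("PIDConfig.A_max must be > 0")
        if self.T <= 0:
            raise ValueError("PIDConfig.T must be > 0")


@dataclass
class PIDState:
    integral: float = 0.0
    e_prev: float = 0.0
    have_prev: bool = False
    last_unclipped: float = 0.0


def tracking_error(y: float, r: float) -> float:
    """Tracking error ``e = y - r`` (output minus reference)."""
    return y - r


def select_gains(e: float, cfg: SMCConfig) -> tuple[float, float]:
    """Heuristic gain switch: ``e > 0 -> (kappa1, rho1)``, else ``(kappa2, rho2)``."""
    if e > 0:
        return cfg.kappa1, cfg.rho1
    return cfg.kappa2, cfg.rho2


def sliding_surface(e: float, e_dot: float, K: float) -> float:
    """Manifold value ``s = K*e + e_dot``."""
    return K * e + e_dot


def _sign(x: float) -> float:
    return math.copysign(1.0, x) if x != 0 else 0.0


def artificial_control(s: float, u_prev: float, K_rho: tuple[float, float],
                       cfg: SMCConfig) -> float:
    """Switching rate ``nu = mu*rho*sign(s*A_max*cos(u_prev))``.

    ``A_max*cos(u_prev)`` is the gradient of the actuating function at the
    current integrator state; it folds the local control authority sign
    into the switching decision.  ``sign(0) = 0``.
    """
    _, rho = K_rho
    return cfg.mu * rho * _sign(s * cfg.A_max * math.cos(u_prev))


def integrate_control(u_prev: float, nu_prev: float, nu: float, T: float) -> float:
    """Trapezoidal update ``u = u_prev + T*(nu + nu_prev)/2``."""
    if T <= 0:
        raise ValueError("T must be > 0")
    return u_prev + T * (nu + nu_prev) / 2.0


def saturate(u: float, A_max: float) -> float:
    """Actuating function ``u_sat = A_max*sin(u)``; always within +-A_max."""
    if A_max <= 0:
        raise ValueError("A_max must be > 0")
    return A_max * math.sin(u)


def smc_step(y: float, r: float, state: SMCState,
             cfg: SMCConfig) -> tuple[float, SMCState]:
    """One controller sample: measurement in, saturated voltage out.

    Composes error -> gain switch -> backward-difference error rate ->
    manifold -> switching rate -> trapezoidal integration -> sine
    saturation, and advances the controller memory.
    """
    if not math.isfinite(y):
        raise FloatingPointError(f"non-finite measurement y={y!r}")
    e = tracking_error(y, r)
    K, rho = select_gains(e, cfg)
    e_dot = (e - state.e_prev) / cfg.T
    s = sliding_surface(e, e_dot, K)
    nu = artificial_control(s, state.u_prev, (K, rho), cfg)
    u = integrate_control(state.u_prev, state.nu_prev, nu, cfg.T)
    u_sat = saturate(u, cfg.A_max)
    return u_sat, SMCState(u_prev=u, nu_prev=nu, e_prev=e,
                           step_index=state.step_index + 1)


def pid_step(y: float, r: float, state: PIDState,
             cfg: PIDConfig) -> tuple[float, PIDState]:
    """One clipped-PID sample.

    Positional PID on ``e = r - y`` (control convention: positive error
    pushes the output up) with trapezoidal integral and backward-difference
    derivative.  The emitted command is clipped to ``[-A_max, +A_max]``
    after computation; the integral is not informed of the clip, so it
    winds up under persistent error.  The unclipped command is kept on the
    state for bound-violation diagnostics.
    """
    e = r - y
    if state.have_prev:
        integral = state.integral + cfg.T * (e + state.e_prev) / 2.0
        deriv = (e - state.e_prev) / cfg.T
    else:
        integral = state.integral + cfg.T * e / 2.0
        deriv = 0.0
    u = cfg.kp * e + cfg.ki * integral + cfg.kd * deriv
    u_clip = min(max(u, -cfg.A_max), cfg.A_max)
    return u_clip, PIDState(integral=integral, e_prev=e, have_prev=True,
                            last_unclipped=u)


class SlidingModeController:
    """Stateful wrapper satisfying the shared controller contract.

    ``step(y, r)`` returns the saturated voltage to apply.  Internally the
    controller bootstraps: the first call only primes the error history and
    returns ``A_max*sin(u_init)`` (the algorithm proper starts at the
    second sample, as the trapezoidal rule needs one sample of history).
    """

    def __init__(self, cfg: SMCConfig):
        self.cfg = cfg
        self.reset()

    def reset(self) -> None:
        self.state: SMCState | None = None
        self.last_u = self.cfg.u_init

    def step(self, y: float, r: float) -> float:
        if self.state is None:
            if not math.isfinite(y):
                raise FloatingPointError(f"non-finite measurement y={y!r}")
            self.state = SMCState(u_prev=self.cfg.u_init, nu_prev=0.0,
                                  e_prev=tracking_error(y, r))
            self.last_u = self.cfg.u_init
            return saturate(self.cfg.u_init, self.cfg.A_max)
        u_sat, self.state = smc_step(y, r, self.state, self.cfg)
        self.last_u = self.state.u_prev
        return u_sat


class PIDController:
    """Stateful hard-clipped PID satisfying the shared controller contract."""

    def __init__(self, cfg: PIDConfig, clip: bool = True):
        self.cfg = cfg
        self.clip = clip
        self.reset()

    def reset(self) -> None:
        self.state = PIDState()
        self.last_u = 0.0

    def step(self, y: float, r: float) -> float:
        u_clip, self.state = pid_step(y, r, self.state, self.cfg)
        self.last_u = self.state.last_unclipped
        return u_clip if self.clip else self.state.last_unclipped
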