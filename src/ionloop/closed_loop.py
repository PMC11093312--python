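"""Reference-trajectory generation and the sampled closed-loop harness.

The loop follows the experimental architecture: at every sampling instant
the output is measured, the error computed, the controller evaluated, and
the resulting voltage applied and held for one full sampling period
(zero-order hold).  Optional zero-mean Gaussian noise on the measurement
emulates the fluctuations a real current readout shows; it is off by
default and fully determined by a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np

__all__ = ["ReferenceSignal", "Trace", "make_reference", "run_closed_loop"]


class Plant(Protocol):
    def apply(self, u_sat: float) -> float: ...
    @property
    def y(self) -> float: ...


class Controller(Protocol):
    def step(self, y: float, r: float) -> float: ...
    def reset(self) -> None: ...
    last_u: float


@dataclass(frozen=True)
class ReferenceSignal:
    """Declarative description of a target trajectory.

    kinds:
      ``constant``        — ``r0`` at every sample;
      ``steps``           — ``r0`` decremented by ``step_delta`` every
                            ``step_period`` seconds;
      ``linear_decline``  — affine from ``r0`` at t=0 to ``r_end`` at the
                            final sample.
    """

    kind: str
    r0: float
    n: int
    T: float = 1.0
    step_delta: float = 0.0
    step_period: float = 400.0
    r_end: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "steps", "linear_decline"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.kind == "steps" and self.step_period <= 0:
            raise ValueError("step_period must be > 0 for stepped references")
        if self.kind == "linear_decline" and self.r_end is None:
            raise ValueError("linear_decline requires r_end")


def make_reference(spec: ReferenceSignal) -> np.ndarray:
    """Materialize the reference as an array of ``n`` samples."""
    t = np.arange(spec.n) * spec.T
    if spec.kind == "constant":
        return np.full(spec.n, float(spec.r0))
    if spec.kind == "steps":
        return spec.r0 - spec.step_delta * np.floor(t / spec.step_period)
    # linear_decline
    if spec.n == 1:
        return np.array([float(spec.r0)])
    return spec.r0 + (spec.r_end - spec.r0) * t / ((spec.n - 1) * spec.T)


@dataclass
class Trace:
    """Per-sample record of a closed-loop run.

    Arrays share one length; ``time`` increases in steps of the sampling
    period.  ``u`` is the controller's raw (pre-saturation) command and
    ``u_sat`` the voltage actually applied.
    """

    time: np.ndarray
    reference: np.ndarray
    output: np.ndarray
    error: np.ndarray
    u: np.ndarray
    u_sat: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("reference", "output", "error", "u", "u_sat"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"Trace.{name} length mismatch")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("Trace.time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self):
        """Trace as a DataFrame with the experiment-log column layout."""
        import pandas as pd

        return pd.DataFrame({
            "d": self.reference,
            "err": self.error,
            "u": self.u_sat,
            "plot_timer": self.time,
            "output": self.output,
            "u_raw": self.u,
        })


def run_closed_loop(plant: Plant, controller: Controller,
                    reference: ReferenceSignal | np.ndarray,
                    n: int | None = None, T: float = 1.0,
                    noise_sd: float = 0.0, seed: int | None = None) -> Trace:
    """Run a sampled closed loop and record every per-sample signal.

    Per sample: measure ``y`` (plus optional seeded Gaussian noise), form
    the error, evaluate the controller, apply the voltage for one period.
    Deterministic given the seed.  Controller or plant faults propagate
    with the failing step index attached.
    """
    if isinstance(reference, ReferenceSignal):
        r = make_reference(reference)
        T = reference.T
    else:
        r = np.asarray(reference, dtype=float)
        if n is not None:
            r = r[:n]
    n = len(r)
    if n == 0:
        raise ValueError("empty reference")

    rng = np.random.default_rng(seed)
    time = np.arange(n) * T
    out = np.empty(n)
    err = np.empty(n)
    u_raw = np.empty(n)
    u_sat = np.empty(n)

    y_true = plant.y
    for i in range(n):
        y = y_true
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        try:
            u = controller.step(y, r[i])
            y_true = plant.apply(u)
        except Exception as exc:
            raise RuntimeError(f"closed loop failed at sample {i}") from exc
        out[i] = y
        err[i] = y - r[i]
        u_raw[i] = getattr(controller, "last_u", math.nan)
        u_sat[i] = u

    return Trace(time=time, reference=r, output=out, error=err,
                 u=u_raw, u_sat=u_sat)
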