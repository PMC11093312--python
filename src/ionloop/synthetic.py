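"""Synthetic stand-ins for the deposited delivery-experiment logs.

The real in vitro logs are device recordings; these generators produce
logs with the same schema, sampling and experiment designs by running the
shipped sliding-mode controller against the simulated pump plant rescaled
to the nA operating point, with seeded Gaussian measurement noise standing
in for readout fluctuation.  They exercise every log-analysis code path,
but they are simulations: numbers computed from them characterize the
model, not the physical device.

Experiment designs (1200 samples at 1 s):

* ``constant`` — hold 1200 nA;
* ``decline``  — linear 1500 -> 900 nA;
* ``steps``    — 1500 nA dropping 300 nA every 400 s.
"""

from __future__ import annotations

import numpy as np

from .closed_loop import ReferenceSignal, Trace, run_closed_loop
from .controllers import SlidingModeController
from .metrics_io import ExperimentLog
from .presets import load_pump_plant, load_smc_config

__all__ = [
    "EXPERIMENT_KINDS",
    "invitro_reference",
    "simulate_invitro_trace",
    "synthetic_experiment_log",
]

EXPERIMENT_KINDS = ("constant", "decline", "steps")

#: Concentration-axis scale mapping the fluorescence-scale pump preset to
#: the nA operating point (1200 nA target at the same relative position of
#: the actuation range as 17.5 on the fluorescence scale).
NA_SCALE = 70.0

#: Measurement-noise standard deviation (nA) of the synthetic readout,
#: the order of the fluctuation the finite readout resolution and fast
#: device transients superimpose on the current signal.
NOISE_SD_NA = 25.0


def invitro_reference(kind: str, n: int = 1200, T: float = 1.0) -> ReferenceSignal:
    """Reference trajectory of one of the three delivery experiment designs."""
    if kind == "constant":
        return ReferenceSignal(kind="constant", r0=1200.0, n=n, T=T)
    if kind == "decline":
        return ReferenceSignal(kind="linear_decline", r0=1500.0, r_end=900.0,
                               n=n, T=T)
    if kind == "steps":
        return ReferenceSignal(kind="steps", r0=1500.0, step_delta=300.0,
                               step_period=400.0, n=n, T=T)
    raise ValueError(f"unknown experiment kind {kind!r}; "
                     f"expected one of {EXPERIMENT_KINDS}")


def simulate_invitro_trace(kind: str, seed: int, n: int = 1200,
                           noise_sd: float = NOISE_SD_NA) -> Trace:
    """Closed-loop SMC run emulating one in vitro experiment design."""
    plant = load_pump_plant("insilico").scaled(NA_SCALE)
    controller = SlidingModeController(load_smc_config("invitro", n=n))
    return run_closed_loop(plant, controller, invitro_reference(kind, n=n),
                           noise_sd=noise_sd, seed=seed)


def synthetic_experiment_log(kind: str, seed: int, n: int = 1200,
                             noise_sd: float = NOISE_SD_NA) -> ExperimentLog:
    """Synthetic log in the deposited four-column layout.

    The ``u`` column holds the applied (saturated) voltage, matching the
    deposited logs whose voltages respect the amplitude bound.
    """
    trace = simulate_invitro_trace(kind, seed, n=n, noise_sd=noise_sd)
    return ExperimentLog(
        d=np.asarray(trace.reference, dtype=float),
        err=np.asarray(trace.error, dtype=float),
        u=np.asarray(trace.u_sat, dtype=float),
        plot_timer=np.asarray(trace.time, dtype=float),
    )
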