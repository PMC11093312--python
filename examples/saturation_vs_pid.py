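"""Structural saturation handling: sliding-mode control vs a clipped PID.

Both controllers regulate the same simulated pump toward a constant
reference near the edge of the actuation range.  The SMC emits
``A_max*sin(u)`` and therefore cannot leave the amplitude; the PID's raw
command shoots far past it and is only usable after an external hard clip.
"""

import numpy as np

from ionloop import (
    PIDController,
    ReferenceSignal,
    SlidingModeController,
    load_pid_config,
    load_pump_plant,
    load_smc_config,
    run_closed_loop,
)

ref = ReferenceSignal(kind="constant", r0=17.5, n=400)

smc = run_closed_loop(load_pump_plant("insilico"),
                      SlidingModeController(load_smc_config("insilico", n=400)),
                      ref)
pid_cfg = load_pid_config("insilico")
pid_raw = run_closed_loop(load_pump_plant("insilico"),
                          PIDController(pid_cfg, clip=False), ref)
pid_clip = run_closed_loop(load_pump_plant("insilico"),
                           PIDController(pid_cfg, clip=True), ref)

A = pid_cfg.A_max
print(f"amplitude limit:              {A} V")
print(f"SMC max |voltage|:            {np.abs(smc.u_sat).max():.3f} V  "
      "(structurally bounded)")
print(f"PID raw max |command|:        {np.abs(pid_raw.u_sat).max():.3f} V  "
      "(violates the limit)")
print(f"PID clipped max |voltage|:    {np.abs(pid_clip.u_sat).max():.3f} V  "
      "(held at the bound by the external clip)")
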