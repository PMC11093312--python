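"""Charge-to-dose conversion and pump calibration fitting.

Integrates a 1200 nA current held for 1200 s, converts the charge to moles
of electrons with Faraday's constant, and scales by the ~20 % delivery
efficiency to get the drug amount (hydrochloride salt, 345.79 g/mol).
Then fits a linear calibration through synthetic (charge, delivered
amount) points, the shape of relationship a chromatography assay provides.
"""

import numpy as np

from ionloop import dose_from_trace, fit_calibration

current = np.full(1201, 1200e-9)  # 1200 nA over 1200 s, 1 s sampling
rep = dose_from_trace(current, eta=20.0, molar_mass=345.79, T=1.0)
print(f"charge passed:        {rep.charge:.3e} C")
print(f"moles of electrons:   {rep.moles_electrons:.4e} mol")
print(f"moles of drug (20%):  {rep.moles_drug:.4e} mol")
print(f"mass of drug:         {rep.mass_drug * 1e6:.3f} ug")

# synthetic calibration points: delivered amount grows linearly with charge
rng = np.random.default_rng(0)
charge = rng.uniform(0.5e-3, 2e-3, size=12)
amount = 2.07e-4 * charge + rng.normal(0, 2e-8, size=12)  # mol per C at ~20%
fit = fit_calibration(np.column_stack([charge, amount]))
print(f"calibration slope:    {fit.slope:.4e} mol/C "
      f"(r^2 = {fit.r_squared:.4f})")
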