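"""Coulometric dose estimation and pump calibration.

Delivered drug is estimated from the pump current: the charge passed is
the time integral of the current, Faraday's constant converts charge to
moles of electrons, and the device efficiency eta (moles of drug delivered
per mole of electrons transferred, in percent — about 20 % for these
pumps) scales electrons to drug.  A linear calibration between measured
current/charge and independently assayed delivered amount can be fitted
from user-supplied points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FARADAY",
    "DoseReport",
    "CalibrationFit",
    "integrate_charge",
    "efficiency",
    "dose_from_trace",
    "fit_calibration",
]

#: Faraday constant, C per mole of electrons.
FARADAY = 96485.33212

#: Molar masses of the delivered drug (g/mol): the hydrochloride salt as
#: loaded in the reservoir, and the free base.
FLUOXETINE_HCL_MOLAR_MASS = 345.79
FLUOXETINE_MOLAR_MASS = 309.33


@dataclass(frozen=True)
class DoseReport:
    """Charge-to-dose conversion summary for one current trace."""

    charge: float            # C
    moles_electrons: float   # mol
    efficiency: float        # %
    moles_drug: float        # mol
    mass_drug: float         # g
    duration: float          # s
    charge_number: int = 1
    has_negative_current: bool = False

    def to_dict(self) -> dict:
        return {
            "charge_C": self.charge,
            "moles_electrons": self.moles_electrons,
            "efficiency_pct": self.efficiency,
            "moles_drug": self.moles_drug,
            "mass_drug_g": self.mass_drug,
            "duration_s": self.duration,
            "charge_number": self.charge_number,
            "has_negative_current": self.has_negative_current,
        }


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line relating integrated charge (or mean current) to delivered amount."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    residual_rms: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def integrate_charge(current: Sequence[float], T: float) -> float:
    """Trapezoidal integral of a uniformly sampled current series (A, s -> C)."""
    current = np.asarray(current, dtype=float)
    if current.size == 0:
        raise ValueError("empty current series")
    if T <= 0:
        raise ValueError("sampling interval T must be > 0")
    if current.size == 1:
        # single sample: treat as constant over one period
        return float(current[0] * T)
    return float(np.trapezoid(current, dx=T))


def efficiency(moles_drug: float, moles_electrons: float) -> float:
    """Delivery efficiency eta = moles drug / moles electrons * 100 %."""
    if moles_electrons <= 0:
        raise ValueError("moles_electrons must be > 0")
    return moles_drug / moles_electrons * 100.0


def dose_from_trace(current: Sequence[float], eta: float, molar_mass: float,
                    T: float = 1.0, charge_number: int = 1) -> DoseReport:
    """Full charge -> electrons -> drug conversion for a current trace.

    ``current`` in amperes, ``eta`` in percent (0, 100], ``molar_mass`` in
    g/mol.  ``charge_number`` is the charge of the delivered species
    (+1 for the protonated drug at the operating pH).  Negative current
    samples are permitted (net charge may decrease) and flagged.
    """
    if not 0 < eta <= 100:
        raise ValueError("eta must be in (0, 100]")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    if charge_number < 1:
        raise ValueError("charge_number must be >= 1")
    current = np.asarray(current, dtype=float)
    charge = integrate_charge(current, T)
    moles_e = charge / FARADAY
    moles_drug = eta / 100.0 * moles_e / charge_number
    duration = (len(current) - 1) * T if len(current) > 1 else T
    return DoseReport(
        charge=charge,
        moles_electrons=moles_e,
        efficiency=eta,
        moles_drug=moles_drug,
        mass_drug=moles_drug * molar_mass,
        duration=float(duration),
        charge_number=charge_number,
        has_negative_current=bool(np.any(current < 0)),
    )


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationFit:
    """Ordinary least-squares line through (charge-or-current, amount) points.

    Exact on collinear input.  The abscissa is whatever the caller measured
    (integrated charge or mean current); the fit does not care, only the
    caller's labelling does.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.all(x == x[0]):
        raise ValueError("degenerate calibration: all x values equal")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        slope_stderr=float(res.stderr),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )
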