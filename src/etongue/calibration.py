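"""Classical single-electrode working-curve calibration.

Fits the log-linear Nikolsky-Eisenman working curve y = a*ln(x) + b per
electrode, for either protocol (direct immersion, or the sample phase of
a standard-addition cycle), and inverts it for single-electrode
concentration prediction.  This is the baseline the learned multivariate
models must beat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class CalibrationFit:
    electrode: str
    method: str  # "DCM" | "MSAM"
    slope: float  # mV per ln(mg/L) (or per log10 if log_base=10)
    intercept: float  # mV
    r_squared: float
    log_base: float = np.e

    def predict(self, concentration: float) -> float:
        return self.slope * self._log(concentration) + self.intercept

    def _log(self, x):
        return np.log(x) if self.log_base == np.e else np.log(x) / np.log(self.log_base)


def fit_loglinear(concentrations: Sequence[float], potentials: Sequence[float],
                  electrode: str = "", method: str = "DCM",
                  log_base: float = np.e) -> CalibrationFit:
    """Least-squares fit of potential against log concentration.

    Natural log by default, matching the fitted working-curve form of the
    emulated electrodes; ``log_base=10`` is available for Nernstian
    log10 practice.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(potentials, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and potentials must be equal-length 1-D")
    if np.any(x <= 0):
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    lx = np.log(x) if log_base == np.e else np.log(x) / np.log(log_base)
    slope, intercept = np.polyfit(lx, y, 1)
    resid = y - (slope * lx + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    return CalibrationFit(electrode, method, float(slope), float(intercept),
                          r2, log_base)


def calibrate_from_records(records, electrode_index: int, ion: str,
                           method: str = "MSAM",
                           log_base: float = np.e) -> CalibrationFit:
    """Working-curve fit for one electrode from measurement records.

    The standard-addition (MSAM) fit regresses the drift-cancelled
    difference Ux - U0 on ln(Cx), so session drift drops out of the
    response; a direct-calibration (DCM) style fit regresses the raw
    sample-phase potential, which retains it.
    """
    conc = np.array([r.targets[ion] for r in records])
    if method.upper() == "MSAM":
        y = np.array([r.ux[electrode_index] - r.u0[electrode_index]
                      for r in records])
    elif method.upper() == "DCM":
        y = np.array([r.ux[electrode_index] for r in records])
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    return fit_loglinear(conc, y, electrode=ion, method=method.upper(),
                         log_base=log_base)


def invert_calibration(fit: CalibrationFit, potential: float) -> float:
    """Concentration (mg/L) at which the working curve predicts ``potential``."""
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    t = (potential - fit.intercept) / fit.slope
    return float(np.exp(t) if fit.log_base == np.e else fit.log_base ** t)
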