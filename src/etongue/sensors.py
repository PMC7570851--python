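"""Digital twin of the ISE sensor array.

Each ion-selective electrode follows a Nikolsky-Eisenman response:

    E = b + s * (T_K / 298.15) * ln(max(c_eff, c_floor)) + drift + noise

where the effective concentration c_eff adds interfering same-charge-sign
ions weighted by selectivity coefficients K_ji and raised to the charge
ratio z_primary/z_i.  Concentrations enter in mg/L with a natural log,
matching the working-curve form the classical calibration module fits.

Two measurement protocols are provided:

* ``measure_dcm`` -- direct calibration: a single immersion reading.
  Session drift contaminates the reading.
* ``measure_msam`` -- multivariate standard addition: a rinsed-water
  baseline reading U0 and a sample reading Ux taken within one session,
  so that any session-constant additive drift cancels in Ux - U0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ions import (
    CHANNEL_ORDER,
    DEFAULT_PANEL,
    ION_ORDER,
    IonSpecies,
    SolutionSample,
    baseline_solution,
)

T_REF_K = 298.15  # 25 degC reference for the configured Nernstian slope
PH_NERNST_MV = 59.16  # glass-electrode slope, mV per pH unit

#: Acquisition quantum (mV): recorded channels are multiples of 2^-20, like a
#: DAQ's finite resolution.  A power of two makes the quantized values exactly
#: representable, so a session-constant (equally quantized) drift offset
#: cancels bit-exactly in Ux - U0.
DAQ_QUANTUM = 2.0 ** -20


def _quantize(x):
    return np.round(np.asarray(x) / DAQ_QUANTUM) * DAQ_QUANTUM


@dataclass
class ElectrodeSpec:
    """Parameters of one ion-selective electrode.

    ``slope`` is the mV-per-ln(mg/L) sensitivity at 25 degC (negative for
    anion electrodes, positive for cation electrodes); ``selectivity``
    maps interfering ions to dimensionless Nikolsky-Eisenman coefficients.
    ``detection_floor`` clamps the log argument (lower linearity limit,
    about 1 mg/L for the commercial electrodes emulated here).
    """

    primary_ion: str
    slope: float
    intercept: float
    selectivity: dict[str, float] = field(default_factory=dict)
    detection_floor: float = 1.0
    noise_sd: float = 0.0
    temperature_coupled: bool = True

    def __post_init__(self) -> None:
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be positive")
        for ion, k in self.selectivity.items():
            if k < 0:
                raise ValueError(f"selectivity[{ion}] must be >= 0")
        z = DEFAULT_PANEL[self.primary_ion].charge
        if z < 0 and self.slope > 0 or z > 0 and self.slope < 0:
            raise ValueError(
                f"{self.primary_ion}: slope sign must match ion charge sign "
                "(negative for anions, positive for cations)"
            )


@dataclass
class SensorArrayConfig:
    """Full sensor-array configuration: six ISEs plus pH and EC transducers."""

    electrodes: list[ElectrodeSpec]
    ec_coefficients: dict[str, float]
    ec_noise_sd: float = 0.0          # uS/cm
    ph_baseline: float = 7.0          # pH of the rinsed-water baseline
    ph_sensitivity: float = 0.6       # pH drop per ln-fold phosphate
    ph_scale: float = 50.0            # mg/L phosphate half-effect scale
    ph_noise_sd: float = 0.0          # pH units
    drift_sd: float = 0.0             # mV-equivalent session drift, all channels
    ionic_strength_beta: float = 0.0  # optional Debye-Hueckel-style attenuation
    session_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.electrodes) != 6:
            raise ValueError("expected exactly 6 ISE specs")
        for v in (self.ec_noise_sd, self.ph_noise_sd, self.drift_sd):
            if v < 0:
                raise ValueError("noise/drift parameters must be >= 0")
        for ion, w in self.ec_coefficients.items():
            if w < 0:
                raise ValueError(f"ec_coefficients[{ion}] must be >= 0")


@dataclass
class MeasurementRecord:
    """One MSAM measurement cycle: baseline and sample potentials of 8 channels."""

    sample_id: str
    u0: np.ndarray
    ux: np.ndarray
    temperature: float
    targets: Optional[dict[str, float]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.u0 = np.asarray(self.u0, dtype=float)
        self.ux = np.asarray(self.ux, dtype=float)
        if self.u0.shape != (8,) or self.ux.shape != (8,):
            raise ValueError("u0 and ux must each hold 8 channel potentials")
        if not (np.all(np.isfinite(self.u0)) and np.all(np.isfinite(self.ux))):
            raise ValueError("non-finite potential in measurement record")


def _ionic_strength(sample: SolutionSample) -> float:
    """Molar ionic strength I = 0.5 sum(c_i z_i^2), c in mol/L."""
    out = 0.0
    for name, sp in DEFAULT_PANEL.items():
        out += 0.5 * (sample.conc(name) / sp.molar_mass * 1e-3) * sp.charge ** 2
    return out


def effective_concentration(sample: SolutionSample, spec: ElectrodeSpec,
                            beta: float = 0.0) -> float:
    """Nikolsky-Eisenman effective concentration seen by one electrode.

    When ``beta > 0`` the result is attenuated by an extended
    Debye-Hueckel activity coefficient, ln(gamma) = -beta z^2 sqrt(I) /
    (1 + sqrt(I)) with molar ionic strength I: electrodes sense
    activities, not concentrations, so every channel carries a
    common-mode imprint of the total (especially divalent) ion load.
    """
    zp = DEFAULT_PANEL[spec.primary_ion].charge
    c_eff = sample.conc(spec.primary_ion)
    for ion, coeff in spec.selectivity.items():
        zi = DEFAULT_PANEL[ion].charge
        if zp * zi <= 0:
            raise ValueError(
                f"{spec.primary_ion}: interference from opposite-sign ion {ion} "
                "is not representable (negative charge-ratio exponent)"
            )
        c_eff += coeff * sample.conc(ion) ** (zp / zi)
    if beta > 0:
        sqrt_i = np.sqrt(_ionic_strength(sample))
        c_eff *= np.exp(-beta * zp ** 2 * sqrt_i / (1.0 + sqrt_i))
    return c_eff


def electrode_emf(sample: SolutionSample, spec: ElectrodeSpec,
                  drift_offset: float = 0.0,
                  rng: Optional[np.random.Generator] = None,
                  ionic_strength_beta: float = 0.0) -> float:
    """Evaluate one electrode's EMF (mV) for a solution.

    The Nernstian slope scales with absolute temperature when
    ``spec.temperature_coupled``; the log argument is clamped at the
    detection floor, so the response is flat below it.
    """
    c_eff = effective_concentration(sample, spec, ionic_strength_beta)
    scale = (sample.temperature + 273.15) / T_REF_K if spec.temperature_coupled else 1.0
    emf = spec.intercept + spec.slope * scale * np.log(max(c_eff, spec.detection_floor))
    emf += drift_offset
    if rng is not None and spec.noise_sd > 0:
        emf += rng.normal(0.0, spec.noise_sd)
    return float(emf)


def simulate_ec_ph(sample: SolutionSample, array: SensorArrayConfig,
                   rng: Optional[np.random.Generator] = None) -> tuple[float, float]:
    """Bulk transducer readings: (EC in uS/cm, pH).

    EC is a conductance-weighted sum over molar concentrations; pH falls
    logarithmically with dihydrogen-phosphate (a weak-acid buffer proxy).
    """
    ec = 0.0
    for ion, w in array.ec_coefficients.items():
        ec += w * sample.conc(ion) / DEFAULT_PANEL[ion].molar_mass
    ph = array.ph_baseline - array.ph_sensitivity * np.log1p(
        sample.conc("H2PO4") / array.ph_scale)
    if rng is not None:
        if array.ec_noise_sd > 0:
            ec += rng.normal(0.0, array.ec_noise_sd)
        if array.ph_noise_sd > 0:
            ph += rng.normal(0.0, array.ph_noise_sd)
    return float(ec), float(ph)


def _read_channels(sample: SolutionSample, array: SensorArrayConfig,
                   drift: np.ndarray,
                   rng: Optional[np.random.Generator]) -> np.ndarray:
    """One pass over all 8 channels (6 ISEs, pH-as-mV, EC) with fixed drift."""
    out = np.empty(8)
    for j, spec in enumerate(array.electrodes):
        out[j] = electrode_emf(sample, spec, drift[j], rng,
                               array.ionic_strength_beta)
    ec, ph = simulate_ec_ph(sample, array, rng)
    out[6] = PH_NERNST_MV * (7.0 - ph) + drift[6]
    out[7] = ec + drift[7]
    return _quantize(out)


def _session_rng(array: SensorArrayConfig, seed: Optional[int]) -> np.random.Generator:
    if seed is None:
        warnings.warn("no seed given; using the array's session_seed "
                      f"({array.session_seed}) for reproducibility")
        seed = array.session_seed
    return np.random.default_rng(seed)


def measure_msam(baseline: SolutionSample, sample: SolutionSample,
                 array: SensorArrayConfig, seed: Optional[int] = None,
                 sample_id: str = "s0") -> MeasurementRecord:
    """One standard-addition measurement cycle.

    One drift offset per channel is drawn for the session and applied to
    BOTH the baseline (U0) and sample (Ux) phases, so it cancels exactly
    in the enriched features Ux - U0.  Both phases are read at the
    sample's bath temperature.
    """
    rng = _session_rng(array, seed)
    drift = (_quantize(rng.normal(0.0, array.drift_sd, 8))
             if array.drift_sd > 0 else np.zeros(8))
    base = baseline.copy()
    base.temperature = sample.temperature
    u0 = _read_channels(base, array, drift, rng)
    ux = _read_channels(sample, array, drift, rng)
    targets = {ion: sample.conc(ion) for ion in ION_ORDER}
    return MeasurementRecord(sample_id, u0, ux, sample.temperature,
                             targets=targets, seed=seed)


def measure_dcm(sample: SolutionSample, array: SensorArrayConfig,
                seed: Optional[int] = None) -> np.ndarray:
    """Direct-calibration reading: 8 channels + temperature, drift NOT cancelled."""
    rng = _session_rng(array, seed)
    drift = (_quantize(rng.normal(0.0, array.drift_sd, 8))
             if array.drift_sd > 0 else np.zeros(8))
    channels = _read_channels(sample, array, drift, rng)
    return np.append(channels, sample.temperature)


def default_array_config(drift_sd: float = 5.0, noise_sd: float = 0.5,
                         ec_noise_sd: float = 20.0, ph_noise_sd: float = 0.02,
                         session_seed: int = 0) -> SensorArrayConfig:
    """The default simulated array.

    Slopes/intercepts emulate commercial electrodes (nitrate, ammonium,
    potassium, calcium, sodium, chloride working curves in mV per
    ln(mg/L)).  Selectivity coefficients are small same-sign cross-terms;
    magnesium couples into the K/Ca/Na electrodes and the EC channel,
    phosphate into the NO3/Cl electrodes, the pH transducer and EC, so
    both electrode-less ions remain inferable from the array.  EC weights
    are equivalent ionic conductances (S cm^2/mol).
    """
    mk = lambda ion, s, b, sel: ElectrodeSpec(ion, s, b, sel, 1.0, noise_sd, True)
    electrodes = [
        mk("NO3", -22.86, 208.47, {"Cl": 0.02, "H2PO4": 0.015}),
        mk("NH4", 22.92, -253.87, {"K": 0.05, "Na": 0.02}),
        mk("K", 23.07, -237.03, {"NH4": 0.03, "Na": 0.01, "Ca": 0.01, "Mg": 0.02}),
        mk("Ca", 11.06, -76.90, {"Mg": 0.35, "Na": 5e-6, "K": 5e-6, "NH4": 5e-6}),
        mk("Na", 19.76, -186.22, {"K": 0.03, "NH4": 0.01, "Ca": 0.02, "Mg": 0.05}),
        mk("Cl", -23.02, 192.33, {"NO3": 0.04, "H2PO4": 0.03}),
    ]
    ec = {"NO3": 71.4, "NH4": 73.5, "K": 73.5, "Ca": 119.0,
          "Na": 50.1, "Cl": 76.3, "H2PO4": 36.0, "Mg": 106.0}
    return SensorArrayConfig(
        electrodes=electrodes, ec_coefficients=ec, ec_noise_sd=ec_noise_sd,
        ph_baseline=7.0, ph_sensitivity=0.6, ph_scale=50.0,
        ph_noise_sd=ph_noise_sd, drift_sd=drift_sd, session_seed=session_seed)


__all__ = [
    "ElectrodeSpec", "SensorArrayConfig", "MeasurementRecord",
    "electrode_emf", "effective_concentration", "simulate_ec_ph",
    "measure_msam", "measure_dcm", "default_array_config",
    "baseline_solution", "CHANNEL_ORDER", "PH_NERNST_MV",
]
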