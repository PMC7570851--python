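"""Ion panel and solution chemistry primitives.

The default panel is the eight nutrient ions of a closed hydroponic
system: nitrate, ammonium, potassium, calcium, sodium, chloride,
dihydrogen phosphate and magnesium.  Six of them are measurable with
commercial ion-selective electrodes (ISEs); phosphate and magnesium are
not, and must be inferred by fusing the array response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class IonSpecies:
    """A dissolved ionic species.

    Parameters
    ----------
    name : str
        Short identifier (e.g. ``"NO3"``).
    charge : int
        Signed valence z; never zero.
    molar_mass : float
        g/mol of the ion as dosed (e.g. 62.0 for NO3-).
    has_electrode : bool
        Whether a dedicated ISE exists for this ion in the array.
    """

    name: str
    charge: int
    molar_mass: float
    has_electrode: bool

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"ion {self.name}: charge must be nonzero")
        if self.molar_mass <= 0:
            raise ValueError(f"ion {self.name}: molar_mass must be positive")


#: Canonical ion ordering used throughout (targets, CSV columns).
ION_ORDER = ("NO3", "NH4", "K", "Ca", "Na", "Cl", "H2PO4", "Mg")

#: Channel ordering of the sensor array: six ISEs then pH and EC.
CHANNEL_ORDER = ("NO3", "NH4", "K", "Ca", "Na", "Cl", "pH", "EC")

DEFAULT_PANEL: dict[str, IonSpecies] = {
    "NO3": IonSpecies("NO3", -1, 62.0, True),
    "NH4": IonSpecies("NH4", +1, 18.0, True),
    "K": IonSpecies("K", +1, 39.1, True),
    "Ca": IonSpecies("Ca", +2, 40.1, True),
    "Na": IonSpecies("Na", +1, 23.0, True),
    "Cl": IonSpecies("Cl", -1, 35.5, True),
    "H2PO4": IonSpecies("H2PO4", -1, 97.0, False),
    "Mg": IonSpecies("Mg", +2, 24.3, False),
}


@dataclass
class SolutionSample:
    """A nutrient solution: ion concentrations (mg/L) plus temperature (degC)."""

    concentrations: dict[str, float] = field(default_factory=dict)
    temperature: float = 25.0

    def __post_init__(self) -> None:
        for ion, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {ion}: {c}")

    def conc(self, ion: str) -> float:
        return self.concentrations.get(ion, 0.0)

    def copy(self) -> "SolutionSample":
        return SolutionSample(dict(self.concentrations), self.temperature)


def baseline_solution(level: float = 1.0, temperature: float = 25.0,
                      panel: Mapping[str, IonSpecies] = DEFAULT_PANEL) -> SolutionSample:
    """Rinsed-water baseline: every panel ion near the ISE detection floor (~1 mg/L)."""
    return SolutionSample({ion: level for ion in panel}, temperature)


def mix_solutions(parts: list[tuple[SolutionSample, float]]) -> SolutionSample:
    """Volume-weighted mixing of solutions (ideal mass balance).

    Parameters
    ----------
    parts : list of (SolutionSample, volume_mL)

    Returns
    -------
    SolutionSample
        Concentration of each ion is the volume-weighted mean; so is the
        temperature (ideal, instantaneous thermal mixing).
    """
    if not parts:
        raise ValueError("mix_solutions: no parts given")
    total = 0.0
    for _, v in parts:
        if v < 0:
            raise ValueError(f"mix_solutions: negative volume {v}")
        total += v
    if total <= 0:
        raise ValueError("mix_solutions: total volume must be positive")
    ions: set[str] = set()
    for s, _ in parts:
        ions.update(s.concentrations)
    mixed = {ion: sum(s.conc(ion) * v for s, v in parts) / total for ion in ions}
    temp = sum(s.temperature * v for s, v in parts) / total
    return SolutionSample(mixed, temp)
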