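"""Mixture-design generation for training-set preparation.

Six designed ions take concentrations from a 10-level grid; a fractional
factorial over those levels gives 27/36/64/100 runs for 3/6/8/10 levels.
The construction is modular (Graeco-Latin style): for L^2 runs indexed by
(i, k) in {0..L-1}^2, factor f gets level (a_f*i + b_f*k) mod L.  Each
factor is exactly level-balanced because gcd(a_f, b_f, L) = 1.  Full
pairwise orthogonality is impossible for composite L with six factors
(over Z2 only three pairwise-independent directions exist), so pairwise
uniformity is guaranteed only up to a small-index subgroup and is tested
as near-balance.  The 27-run case uses a three-index analogue over
{0,1,2}^3 with pairwise linearly independent coefficient triples, which
IS pairwise orthogonal.

The two electrode-less ions (dihydrogen phosphate, magnesium) and the
bath temperature are drawn uniformly at random per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ions import SolutionSample, baseline_solution
from .sensors import MeasurementRecord, SensorArrayConfig, measure_msam

#: Designed (ISE) ions, in design-column order.
DESIGN_IONS = ("NO3", "NH4", "K", "Ca", "Na", "Cl")

#: Default 10-level concentration grid (mg/L) per designed ion.
DEFAULT_LEVELS: dict[str, tuple[float, ...]] = {
    "NO3": (44, 88, 177, 221, 332, 442, 553, 769, 1106, 1328),
    "NH4": (6, 10, 15, 20, 25, 35, 45, 55, 75, 120),
    "K": (15, 50, 75, 100, 150, 175, 200, 225, 350, 500),
    "Ca": (10, 25, 50, 75, 100, 125, 175, 225, 250, 350),
    "Na": (5, 12, 25, 35, 50, 100, 150, 175, 250, 300),
    "Cl": (5, 15, 35, 50, 80, 125, 175, 200, 300, 350),
}

#: Modular-construction coefficients per supported level count.  Chosen so
#: every factor is balanced and pairwise cross-tables collapse at worst onto
#: an index-2 (or, at L=6, index-3) subgroup.
_COEFFS_2D: dict[int, list[tuple[int, int]]] = {
    6: [(1, 0), (0, 1), (1, 1), (1, 2), (2, 1), (1, 3)],
    8: [(1, 0), (0, 1), (1, 1), (1, 2), (2, 1), (1, 3)],
    10: [(1, 0), (0, 1), (1, 1), (1, 2), (2, 1), (3, 7)],
}
_COEFFS_3D = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1), (1, 2, 1), (1, 1, 2)]

RUNS_BY_LEVELS = {3: 27, 6: 36, 8: 64, 10: 100}


@dataclass
class LevelTable:
    """Ordered concentration levels (mg/L) per designed ion."""

    levels: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_LEVELS))

    def __post_init__(self) -> None:
        for ion in DESIGN_IONS:
            if ion not in self.levels:
                raise ValueError(f"level table missing ion {ion}")
            seq = tuple(self.levels[ion])
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(f"levels for {ion} must be strictly increasing")
            self.levels[ion] = seq

    @property
    def n_levels(self) -> int:
        return len(self.levels[DESIGN_IONS[0]])

    def subset_indices(self, n: int) -> np.ndarray:
        """Evenly spread ``n`` of the available levels (always includes ends)."""
        return np.round(np.linspace(0, self.n_levels - 1, n)).astype(int)

    def concentration(self, ion: str, level_index: int, n_levels: int) -> float:
        idx = self.subset_indices(n_levels)
        if not 0 <= level_index < n_levels:
            raise IndexError(f"level index {level_index} out of range for "
                             f"{n_levels}-level design")
        return float(self.levels[ion][idx[level_index]])


@dataclass
class DesignSpec:
    """Fractional-factorial design specification."""

    n_levels: int = 10
    n_factors: int = 6
    seed: int = 0
    aux_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"H2PO4": (6.0, 678.0), "Mg": (6.0, 125.0)})
    temperature_range: tuple[float, float] = (15.0, 35.0)
    aux_log_uniform: bool = False

    def __post_init__(self) -> None:
        if self.n_levels not in RUNS_BY_LEVELS:
            raise ValueError(f"n_levels must be one of {sorted(RUNS_BY_LEVELS)}")
        if self.n_factors != len(DESIGN_IONS):
            raise ValueError("this design targets exactly 6 ion factors")

    @property
    def n_runs(self) -> int:
        return RUNS_BY_LEVELS[self.n_levels]


def factorial_design(spec: DesignSpec) -> np.ndarray:
    """Level-index matrix of shape (n_runs, n_factors), each factor balanced."""
    L = spec.n_levels
    if L == 3:
        coeffs = np.array(_COEFFS_3D)
        grid = np.array([(i, k, m) for i in range(3) for k in range(3)
                         for m in range(3)])
        return (grid @ coeffs.T) % 3
    coeffs = np.array(_COEFFS_2D[L])
    grid = np.array([(i, k) for i in range(L) for k in range(L)])
    return (grid @ coeffs.T) % L


def realize_samples(design: np.ndarray, levels: LevelTable,
                    spec: DesignSpec) -> list[SolutionSample]:
    """Map level indices to concentrations; draw aux ions and temperature."""
    rng = np.random.default_rng(spec.seed)
    samples = []
    for row in np.asarray(design):
        conc = {ion: levels.concentration(ion, int(row[f]), spec.n_levels)
                for f, ion in enumerate(DESIGN_IONS)}
        for ion, (lo, hi) in spec.aux_ranges.items():
            if spec.aux_log_uniform:
                conc[ion] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                conc[ion] = float(rng.uniform(lo, hi))
        temp = float(rng.uniform(*spec.temperature_range))
        samples.append(SolutionSample(conc, temp))
    return samples


def build_dataset(spec: DesignSpec, levels: LevelTable,
                  array: SensorArrayConfig) -> tuple[list[SolutionSample],
                                                     list[MeasurementRecord]]:
    """Run the full protocol: design -> solutions -> MSAM measurement records.

    Each record gets an independent per-session seed derived from the
    design seed, emulating one measurement session per sample.
    """
    design = factorial_design(spec)
    samples = realize_samples(design, levels, spec)
    baseline = baseline_solution(1.0)
    records = []
    for i, s in enumerate(samples):
        rec_seed = int(np.random.SeedSequence([spec.seed, i]).generate_state(1)[0]
                       % 2**31)
        records.append(measure_msam(baseline, s, array, seed=rec_seed,
                                    sample_id=f"s{i:03d}"))
    return samples, records


def pairwise_chi_square(design: np.ndarray, f1: int, f2: int) -> float:
    """Chi-square of the two-factor level cross-table against uniformity."""
    design = np.asarray(design)
    L = int(design.max()) + 1
    n = design.shape[0]
    expected = n / L**2
    table = np.zeros((L, L))
    for a, b in design[:, [f1, f2]]:
        table[a, b] += 1
    return float(((table - expected) ** 2 / expected).sum())
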