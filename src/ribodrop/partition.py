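"""Two-phase RNA partitioning between coacervate and supernatant.

A sample of initial concentration c_ini in volume V_ini separates into a
small coacervate phase (V_coac) and supernatant (V_sup).  Per-phase
fluorescence intensities give the fraction of RNA in each phase,

    F_phase = I_phase / (I_coac + I_sup),

per-phase concentrations follow from the dilution bookkeeping,

    c_phase = F_phase · c_ini · V_ini / V_phase,

and the partition coefficient is K = c_coac / c_sup.  The same mass
balance, inverted, predicts the concentration inside coacervate
microdroplets from a known K when a small volume of RNA-loaded coacervate
is dispersed in supernatant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PartitionMeasurement",
    "PartitionResult",
    "phase_fraction",
    "phase_concentration",
    "partition_coefficient",
    "analyze_measurement",
    "droplet_concentration_from_K",
]


@dataclass(frozen=True)
class PartitionMeasurement:
    """Fluorescence intensities and volumes of the two separated phases."""

    I_coac: float        # a.u.
    I_sup: float         # a.u.
    c_ini: float         # µM
    V_ini: float         # µl
    V_coac: float        # µl

    def __post_init__(self) -> None:
        if self.I_coac < 0 or self.I_sup < 0:
            raise ValueError("intensities must be nonnegative")
        if self.I_coac == 0 and self.I_sup == 0:
            raise ValueError("both phase intensities are zero")
        if not (0 < self.V_coac < self.V_ini):
            raise ValueError("volumes must satisfy 0 < V_coac < V_ini")
        if not self.c_ini > 0:
            raise ValueError("c_ini must be positive")

    @property
    def V_sup(self) -> float:
        return self.V_ini - self.V_coac


@dataclass(frozen=True)
class PartitionResult:
    F_coac: float
    F_sup: float
    c_coac: float        # µM
    c_sup: float         # µM
    K: float             # dimensionless; inf when c_sup == 0

    @property
    def K_unbounded(self) -> bool:
        """True when all signal was in the coacervate phase (c_sup = 0)."""
        return math.isinf(self.K)


def phase_fraction(I_phase: float, I_other: float) -> float:
    """Fraction of RNA in one phase from the two phase intensities."""
    if I_phase < 0 or I_other < 0:
        raise ValueError("intensities must be nonnegative")
    total = I_phase + I_other
    if total == 0:
        raise ValueError("total intensity is zero")
    return I_phase / total


def phase_concentration(
    F: float, c_ini: float, V_ini: float, V_phase: float
) -> float:
    """Concentration (µM) in a phase holding fraction F of the RNA."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    if not V_phase > 0 or not V_ini > 0:
        raise ValueError("volumes must be positive")
    return F * c_ini * V_ini / V_phase


def partition_coefficient(c_coac: float, c_sup: float) -> float:
    """K = c_coac / c_sup.  Returns inf (flagged, not a crash) at c_sup = 0."""
    if c_sup < 0 or c_coac < 0:
        raise ValueError("concentrations must be nonnegative")
    if c_sup == 0:
        return math.inf  # K unbounded: no detectable RNA in the supernatant
    return c_coac / c_sup


def analyze_measurement(m: PartitionMeasurement) -> PartitionResult:
    """Full fraction → concentration → K chain for one measurement."""
    F_coac = phase_fraction(m.I_coac, m.I_sup)
    F_sup = 1.0 - F_coac
    c_coac = phase_concentration(F_coac, m.c_ini, m.V_ini, m.V_coac)
    c_sup = phase_concentration(F_sup, m.c_ini, m.V_ini, m.V_sup)
    return PartitionResult(F_coac, F_sup, c_coac, c_sup,
                           partition_coefficient(c_coac, c_sup))


def droplet_concentration_from_K(
    K: float, c_total: float, V_coac: float, V_total: float
) -> tuple[float, float]:
    """Predict (c_coac, c_sup) in µM when V_coac of coacervate holding all
    the RNA at overall concentration c_total is dispersed in V_total.

    Solves the mass balance c_coac·V_coac + c_sup·(V_total − V_coac)
    = c_total·V_total together with the equilibrium c_coac = K·c_sup.
    """
    if not K > 0:
        raise ValueError("K must be positive")
    if not 0 < V_coac < V_total:
        raise ValueError("volumes must satisfy 0 < V_coac < V_total")
    if not c_total > 0:
        raise ValueError("c_total must be positive")
    c_sup = c_total * V_total / (K * V_coac + (V_total - V_coac))
    return K * c_sup, c_sup
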