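"""Parameter presets and noise specification for synthetic-data generation.

The packaged :data:`CMDEX_PLYS` preset collects the kinetic, transport and
partitioning constants reported for the CM-Dex:PLys (4:1) coacervate /
hammerhead-ribozyme system: single-turnover cleavage rate constants in
buffer, bulk coacervate phase and coacervate microdroplets, FRAP-derived
diffusion coefficients and whole-droplet exchange times, partition
coefficients of the 39-nt ribozyme and its 12-nt FRET substrate, and the
sample volumes used in the partitioning and microdroplet experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

__all__ = ["ParameterPreset", "NoiseSpec", "CMDEX_PLYS", "get_preset", "PRESETS"]


@dataclass(frozen=True)
class ParameterPreset:
    """Named bundle of model constants for one experimental system.

    Rates are 1/min (cleavage kinetics) unless noted; FRAP quantities are in
    seconds and µm; volumes in µl; concentrations in µM; temperature in K.
    """

    name: str
    # cleavage kinetics (1/min)
    k0_buffer: float = 0.6          # mono-exponential rate, aqueous buffer
    k0_gel_buffer: float = 0.38     # same reaction quantified by gel bands
    k1_bulk: float = 1.0e-2         # fast phase, bulk coacervate
    k2_bulk: float = 1.5e-4         # slow phase, bulk coacervate
    A1_bulk: float = 0.5            # fast-phase amplitude fraction
    k1_droplet: float = 4.4e-2      # fast phase, coacervate microdroplets
    k2_droplet: float = 2.3e-3      # slow phase, coacervate microdroplets
    A1_droplet: float = 0.5
    # FRAP / transport
    D_ribozyme: float = 1.0         # µm²/s, spot FRAP in bulk coacervate
    D_substrate: float = 1.6        # µm²/s
    r_bleach: float = 2.0           # µm, bleach-spot radius
    tau_wd_substrate: float = 22.0  # s, whole-droplet exchange time
    tau_wd_ribozyme: float = 189.0  # s
    # partitioning
    K_ribozyme: float = 9600.0
    K_substrate: float = 3000.0
    # intensity calibration
    fret_effect: float = 1.69       # cleaved/uncleaved quantum-yield ratio
    # RNA lengths (nt)
    N_ribozyme: int = 39
    N_substrate: int = 12
    N_product: int = 6
    temperature: float = 298.15     # K (assays at 25 °C)
    # volumes (µl) and loadings (µM)
    V_coac_partition: float = 3.0
    V_ini_partition: float = 150.0
    V_coac_droplet: float = 1.0
    V_total_droplet: float = 50.0
    c_total_ribozyme: float = 1.0
    c_total_substrate: float = 0.5
    # gel-timecourse intensity parameters (a.u.); spans chosen so that the
    # cleaved/uncleaved span ratio equals fret_effect
    gel_offset_C: float = 0.05
    gel_Imax_uncleaved: float = 1.05

    @property
    def gel_Imax_cleaved(self) -> float:
        """Cleaved-band plateau: uncleaved span scaled by the FRET effect."""
        return self.fret_effect * (self.gel_Imax_uncleaved - self.gel_offset_C)

    def __post_init__(self) -> None:
        positive = (
            "k0_buffer", "k0_gel_buffer", "k1_bulk", "k2_bulk", "k1_droplet",
            "k2_droplet", "D_ribozyme", "D_substrate", "r_bleach",
            "tau_wd_substrate", "tau_wd_ribozyme", "fret_effect",
            "temperature", "V_coac_partition", "V_ini_partition",
            "V_coac_droplet", "V_total_droplet", "c_total_ribozyme",
            "c_total_substrate",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("A1_bulk", "A1_droplet"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("K_ribozyme", "K_substrate"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 (solutes enrich in the coacervate)")
        if not self.k1_bulk > self.k2_bulk:
            raise ValueError("k1_bulk must exceed k2_bulk")
        if not self.k1_droplet > self.k2_droplet:
            raise ValueError("k1_droplet must exceed k2_droplet")
        for name in ("N_ribozyme", "N_substrate", "N_product"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 1):
                raise ValueError(f"{name} must be a positive integer")

    # -- flat key=value serialisation ------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterPreset":
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"line {lineno}: unknown preset key {key!r}")
            if key == "name":
                kwargs[key] = value
            elif key.startswith("N_"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "ParameterPreset":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian intensity noise with a reproducible seed."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(values, dtype=float)
        return np.asarray(values, dtype=float) + self.rng().normal(
            0.0, self.sigma, size=np.shape(values)
        )


#: Reported constants for the CM-Dex:PLys (4:1 molar ratio) system.
CMDEX_PLYS = ParameterPreset(name="cmdex_plys")

PRESETS = {CMDEX_PLYS.name: CMDEX_PLYS}


def get_preset(name: str) -> ParameterPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
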