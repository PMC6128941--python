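"""Synthetic-data generators for every input the analysis pipeline consumes.

Each generator evaluates the closed-form model the corresponding analysis
module fits (product-formation kinetics, gel band decays, FRAP recovery,
two-phase partitioning intensities) and adds seeded i.i.d. Gaussian noise.
With sigma = 0 the output reproduces the model to machine precision, so
every fitting routine can be exercised in exact-recovery mode; preset
helpers generate the traces corresponding to the packaged study constants.
"""

from __future__ import annotations

import numpy as np

from .frap import FrapTrace, frap_model, tau_from_diffusion
from .kinetics import GelTimecourse, KineticTrace, biexp_model, mono_model
from .partition import PartitionMeasurement
from .presets import CMDEX_PLYS, NoiseSpec, ParameterPreset

__all__ = [
    "generate_fret_trace",
    "generate_gel_timecourse",
    "generate_frap_trace",
    "generate_partition_measurement",
    "preset_fret_trace",
    "preset_gel_timecourse",
    "preset_frap_trace",
    "preset_partition_measurement",
]

_NO_NOISE = NoiseSpec(0.0, 0)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least 2 points")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def generate_fret_trace(
    model: str,
    times: np.ndarray,
    *,
    k0: float | None = None,
    k1: float | None = None,
    k2: float | None = None,
    A1: float | None = None,
    t0: float = 0.0,
    condition: str = "buffer",
    noise: NoiseSpec = _NO_NOISE,
) -> KineticTrace:
    """Normalised product-formation trace from the mono or bi model.

    ``model`` is "mono" (needs k0) or "bi" (needs k1, k2, A1); rates are
    1/min, times minutes.  Noiseless output equals the model exactly.
    """
    times = _check_times(times)
    if model == "mono":
        if k0 is None or not k0 > 0:
            raise ValueError("mono model needs a strictly positive rate k0")
        clean = mono_model(times, 1.0 / k0, t0)
    elif model == "bi":
        if k1 is None or k2 is None or A1 is None:
            raise ValueError("bi model needs k1, k2 and A1")
        if not (k1 > 0 and k2 > 0):
            raise ValueError("rates must be strictly positive")
        if not 0.0 <= A1 <= 1.0:
            raise ValueError("A1 must lie in [0, 1]")
        clean = biexp_model(times, 1.0 / k1, 1.0 / k2, A1, t0)
    else:
        raise ValueError("model must be 'mono' or 'bi'")
    return KineticTrace(times, noise.apply(clean), condition=condition, t0=t0)


def generate_gel_timecourse(
    tau: float,
    C: float,
    Imax_cleaved: float,
    Imax_uncleaved: float,
    times: np.ndarray,
    noise: NoiseSpec = _NO_NOISE,
) -> GelTimecourse:
    """Cleaved/uncleaved band timecourses sharing one time constant.

    cleaved(t)   = Imax_cleaved·(1 − e^{−t/tau}) + C
    uncleaved(t) = C + (Imax_uncleaved − C)·e^{−t/tau}
    """
    times = _check_times(times)
    if not tau > 0:
        raise ValueError("tau must be strictly positive")
    if not (Imax_cleaved > 0 and Imax_uncleaved > 0):
        raise ValueError("Imax values must be positive")
    decay = np.exp(-times / tau)
    cleaved = Imax_cleaved * (1.0 - decay) + C
    uncleaved = C + (Imax_uncleaved - C) * decay
    rng = noise.rng()
    if noise.sigma > 0:
        cleaved = cleaved + rng.normal(0.0, noise.sigma, times.size)
        uncleaved = uncleaved + rng.normal(0.0, noise.sigma, times.size)
    return GelTimecourse(times, cleaved, uncleaved)


def generate_frap_trace(
    mode: str,
    times: np.ndarray,
    *,
    A: float = 1.0,
    tau: float | None = None,
    D: float | None = None,
    r: float | None = None,
    t_bleach: float = 0.0,
    noise: NoiseSpec = _NO_NOISE,
) -> FrapTrace:
    """FRAP recovery curve: 1 pre-bleach, 1 − A·e^{−(t−t_bleach)/tau} after.

    Supply exactly one of ``tau`` (s) or ``(D, r)``; in the latter case the
    spot-recovery time constant is derived from the half-time relation,
    tau = 0.88 r²/(4 ln2 · D).
    """
    times = _check_times(times)
    if (tau is None) == (D is None):
        raise ValueError("supply exactly one of tau or (D, r)")
    if D is not None:
        if r is None:
            raise ValueError("D requires the bleach radius r")
        tau = tau_from_diffusion(D, r)
    if not tau > 0:
        raise ValueError("tau must be strictly positive")
    if not 0.0 < A <= 1.0:
        raise ValueError("bleach depth A must lie in (0, 1]")
    if not times[0] <= t_bleach <= times[-1]:
        raise ValueError("bleach time must lie within the time grid")
    clean = frap_model(times, A, tau, t_bleach)
    return FrapTrace(times, noise.apply(clean), t_bleach=t_bleach, mode=mode, r=r)


def generate_partition_measurement(
    K: float,
    c_ini: float,
    V_coac: float,
    V_ini: float,
    noise: NoiseSpec = _NO_NOISE,
    I_total: float = 1000.0,
) -> PartitionMeasurement:
    """Two-phase intensities consistent with partition coefficient K.

    Phase fractions follow from the equilibrium: the coacervate holds
    F = K·V_coac / (K·V_coac + V_sup) of the RNA; intensities are those
    fractions of ``I_total`` plus noise.
    """
    if not K > 0:
        raise ValueError("K must be positive")
    if not 0 < V_coac < V_ini:
        raise ValueError("volumes must satisfy 0 < V_coac < V_ini")
    V_sup = V_ini - V_coac
    F_coac = K * V_coac / (K * V_coac + V_sup)
    I_coac, I_sup = F_coac * I_total, (1.0 - F_coac) * I_total
    if noise.sigma > 0:
        rng = noise.rng()
        I_coac = max(I_coac + rng.normal(0.0, noise.sigma), 0.0)
        I_sup = max(I_sup + rng.normal(0.0, noise.sigma), 0.0)
    return PartitionMeasurement(
        I_coac=float(I_coac), I_sup=float(I_sup),
        c_ini=c_ini, V_ini=V_ini, V_coac=V_coac,
    )


# ---------------------------------------------------------------------------
# preset-driven convenience generators

def preset_fret_trace(
    condition: str,
    times: np.ndarray | None = None,
    preset: ParameterPreset = CMDEX_PLYS,
    noise: NoiseSpec = _NO_NOISE,
) -> KineticTrace:
    """Cleavage trace for one study condition: buffer (mono, 0-10 min),
    bulk coacervate (bi, 0-530 min) or microdroplets (bi, 0-900 min)."""
    if condition == "buffer":
        if times is None:
            times = np.arange(0.0, 10.0 + 1e-9, 0.1)
        return generate_fret_trace(
            "mono", times, k0=preset.k0_buffer, condition="buffer", noise=noise
        )
    if condition == "bulk":
        if times is None:
            times = np.arange(0.0, 530.0 + 1e-9, 1.0)
        return generate_fret_trace(
            "bi", times, k1=preset.k1_bulk, k2=preset.k2_bulk,
            A1=preset.A1_bulk, condition="bulk", noise=noise,
        )
    if condition == "droplet":
        if times is None:
            times = np.arange(0.0, 900.0 + 1e-9, 1.0)
        return generate_fret_trace(
            "bi", times, k1=preset.k1_droplet, k2=preset.k2_droplet,
            A1=preset.A1_droplet, condition="droplet", noise=noise,
        )
    raise ValueError("condition must be 'buffer', 'bulk' or 'droplet'")


def preset_gel_timecourse(
    times: np.ndarray | None = None,
    preset: ParameterPreset = CMDEX_PLYS,
    noise: NoiseSpec = _NO_NOISE,
) -> GelTimecourse:
    """Gel band timecourse at the buffer gel rate with spans whose ratio
    reproduces the preset FRET-effect factor."""
    if times is None:
        times = np.arange(0.0, 20.0 + 1e-9, 0.5)
    return generate_gel_timecourse(
        tau=1.0 / preset.k0_gel_buffer, C=preset.gel_offset_C,
        Imax_cleaved=preset.gel_Imax_cleaved,
        Imax_uncleaved=preset.gel_Imax_uncleaved,
        times=times, noise=noise,
    )


def preset_frap_trace(
    species: str,
    mode: str,
    times: np.ndarray | None = None,
    preset: ParameterPreset = CMDEX_PLYS,
    noise: NoiseSpec = _NO_NOISE,
) -> FrapTrace:
    """FRAP trace for ribozyme or substrate in either bleach geometry.

    Whole-droplet mode uses the exchange time constants (22 s substrate,
    189 s ribozyme); spot mode derives tau from the preset diffusion
    coefficient and bleach radius.
    """
    if species not in ("ribozyme", "substrate"):
        raise ValueError("species must be 'ribozyme' or 'substrate'")
    if mode == "whole_droplet":
        tau = (preset.tau_wd_ribozyme if species == "ribozyme"
               else preset.tau_wd_substrate)
        if times is None:
            t_end = 600.0 if species == "ribozyme" else 100.0
            step = 1.0 if species == "ribozyme" else 0.5
            times = np.arange(-5.0, t_end + 1e-9, step)
        return generate_frap_trace(mode, times, tau=tau, noise=noise)
    if mode == "spot":
        D = preset.D_ribozyme if species == "ribozyme" else preset.D_substrate
        if times is None:
            tau = tau_from_diffusion(D, preset.r_bleach)
            times = np.arange(-1.0, 10.0 * tau + 1e-9, tau / 20.0)
        return generate_frap_trace(
            mode, times, D=D, r=preset.r_bleach, noise=noise
        )
    raise ValueError("mode must be 'spot' or 'whole_droplet'")


def preset_partition_measurement(
    species: str,
    preset: ParameterPreset = CMDEX_PLYS,
    noise: NoiseSpec = _NO_NOISE,
) -> PartitionMeasurement:
    """Partition measurement at the preset K and partitioning volumes."""
    if species == "ribozyme":
        K = preset.K_ribozyme
    elif species == "substrate":
        K = preset.K_substrate
    else:
        raise ValueError("species must be 'ribozyme' or 'substrate'")
    return generate_partition_measurement(
        K=K, c_ini=preset.c_total_substrate,
        V_coac=preset.V_coac_partition, V_ini=preset.V_ini_partition,
        noise=noise,
    )
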