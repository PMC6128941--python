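"""FRAP analysis: recovery fits, diffusion coefficients and viscosity.

Two bleaching geometries are handled.  Spot FRAP (a small bleached region
inside the bulk coacervate phase) probes lateral diffusion: the fitted
recovery time constant tau is converted to a diffusion coefficient via the
half-time approximation

    D = 0.88 r^2 / (4 ln 2 · tau),

where r is the bleach-spot radius and tau·ln2 is the recovery half time.
Whole-droplet FRAP (the entire droplet bleached) probes exchange of
molecules between a droplet and its exterior; its tau is an exchange time
and is deliberately never converted to a diffusion coefficient.

Viscosity of the coacervate phase is estimated from D by Stokes-Einstein,
eta = kB·T / (6 pi R_h D), with the hydrodynamic radius of an RNA of N
nucleotides modelled as the power law R_h = 5e-10 · N^0.38 m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .kinetics import FitError, _multistart_least_squares

__all__ = [
    "FrapTrace",
    "FrapFit",
    "DiffusionResult",
    "ViscosityResult",
    "normalize_frap",
    "fit_recovery",
    "diffusion_from_tau",
    "diffusion_from_fit",
    "tau_from_diffusion",
    "hydrodynamic_radius",
    "hydrodynamic_radius_bounds",
    "viscosity",
    "frap_model",
    "BOLTZMANN_J_PER_K",
]

BOLTZMANN_J_PER_K = 1.380649e-23

# R_h = _RH_COEFF_M * N ** _RH_EXPONENT (metres); the quoted uncertainties
# are carried for optional propagation, central values define estimates.
_RH_COEFF_M = 5e-10
_RH_COEFF_SD = 0.28e-10
_RH_EXPONENT = 0.38
_RH_EXPONENT_SD = 0.01


@dataclass
class FrapTrace:
    """Normalised FRAP recovery curve (pre-bleach intensity = 1).

    times in seconds; ``mode`` is "spot" or "whole_droplet"; ``r`` is the
    bleach-spot radius in µm and is required in spot mode.
    """

    times: np.ndarray
    intensities: np.ndarray
    t_bleach: float = 0.0
    mode: str = "spot"
    r: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be 1-D and equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.mode not in ("spot", "whole_droplet"):
            raise ValueError("mode must be 'spot' or 'whole_droplet'")
        if self.mode == "spot":
            if self.r is None or not self.r > 0:
                raise ValueError("spot mode requires a positive bleach radius r")


@dataclass(frozen=True)
class FrapFit:
    A: float              # bleach depth, in (0, 1]
    tau: float            # s
    sse: float
    n_points: int
    converged: bool = True


@dataclass(frozen=True)
class DiffusionResult:
    D: float              # µm²/s
    r: float              # µm
    tau: float            # s


@dataclass(frozen=True)
class ViscosityResult:
    eta: float            # mPa·s
    R_h: float            # nm
    T: float              # K
    D: float              # µm²/s
    N: int                # nt


def frap_model(
    t: np.ndarray, A: float, tau: float, t_bleach: float = 0.0
) -> np.ndarray:
    """Piecewise recovery: 1 before the bleach, exponential return after."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    post = t >= t_bleach
    out[post] = 1.0 - A * np.exp(-(t[post] - t_bleach) / tau)
    return out


def normalize_frap(
    times: np.ndarray,
    bleach_roi: np.ndarray,
    reference_roi: np.ndarray,
    background_roi: np.ndarray | None = None,
    whole_droplet_series: np.ndarray | None = None,
    *,
    t_bleach: float = 0.0,
    mode: str = "spot",
    r: float | None = None,
) -> FrapTrace:
    """Build a normalised FRAP trace from raw region-of-interest series.

    The bleached-region intensity is background-subtracted and divided by
    the (background-subtracted) reference region, removing acquisition
    bleaching and lamp drift.  For whole-droplet FRAP an additional
    division by the whole-droplet intensity is applied.  Finally the curve
    is scaled so the pre-bleach mean is exactly 1.
    """
    times = np.asarray(times, dtype=float)
    bleach = np.asarray(bleach_roi, dtype=float)
    ref = np.asarray(reference_roi, dtype=float)
    bg = np.zeros_like(bleach) if background_roi is None else np.asarray(
        background_roi, dtype=float
    )
    if not (times.shape == bleach.shape == ref.shape == bg.shape):
        raise ValueError("ROI series must share one time grid")
    if np.any(ref <= bg):
        raise ValueError("reference intensity must exceed background at every point")
    curve = (bleach - bg) / (ref - bg)
    if whole_droplet_series is not None:
        whole = np.asarray(whole_droplet_series, dtype=float)
        if whole.shape != times.shape:
            raise ValueError("whole-droplet series must share the time grid")
        curve = curve / whole
    pre = times < t_bleach
    if not np.any(pre):
        raise ValueError("need at least one pre-bleach sample to normalise")
    curve = curve / np.mean(curve[pre])
    return FrapTrace(times, curve, t_bleach=t_bleach, mode=mode, r=r)


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Fit 1 - A·exp(-(t - t_bleach)/tau) to the post-bleach samples."""
    post = trace.times >= trace.t_bleach
    if np.count_nonzero(post) < 3:
        raise FitError("recovery fit needs at least 3 post-bleach points")
    t = trace.times[post] - trace.t_bleach
    y = trace.intensities[post]

    def residual(p):
        return (1.0 - p[0] * np.exp(-t / p[1])) - y

    span = max(t[-1], 1e-6)
    starts = [[a, tau] for a in (0.5, 1.0)
              for tau in np.geomspace(max(span / 1e3, 1e-6), span * 10, 6)]
    best = _multistart_least_squares(
        residual, starts, ([1e-12, 1e-12], [1.0, 1e12])
    )
    if best is None:
        return FrapFit(np.nan, np.nan, np.inf, int(np.count_nonzero(post)),
                       converged=False)
    A, tau = map(float, best.x)
    return FrapFit(A, tau, float(2 * best.cost), int(np.count_nonzero(post)),
                   converged=bool(best.success))


def diffusion_from_tau(tau: float, r: float) -> DiffusionResult:
    """Convert a spot-FRAP time constant to a diffusion coefficient,
    D = 0.88 r²/(4 ln2 · tau)."""
    if not tau > 0 or not r > 0:
        raise ValueError("tau and r must be strictly positive")
    D = 0.88 * r * r / (4.0 * np.log(2.0) * tau)
    return DiffusionResult(D=float(D), r=float(r), tau=float(tau))


def tau_from_diffusion(D: float, r: float) -> float:
    """Inverse of :func:`diffusion_from_tau`: the tau a spot bleach of
    radius r recovers with at diffusion coefficient D."""
    if not D > 0 or not r > 0:
        raise ValueError("D and r must be strictly positive")
    return float(0.88 * r * r / (4.0 * np.log(2.0) * D))


def diffusion_from_fit(fit: FrapFit, trace: FrapTrace) -> DiffusionResult:
    """Diffusion coefficient from a fitted spot-FRAP trace.

    Whole-droplet traces are rejected: their tau measures droplet/exterior
    exchange, not lateral diffusion, and must not be fed to the spot
    conversion.
    """
    if trace.mode != "spot":
        raise ValueError(
            "diffusion conversion is only valid for spot FRAP; "
            "whole-droplet tau is an exchange time"
        )
    return diffusion_from_tau(fit.tau, trace.r)


def hydrodynamic_radius(N: int) -> float:
    """Hydrodynamic radius (nm) of an RNA of N nucleotides,
    R_h = 5e-10 · N^0.38 m."""
    if not (float(N).is_integer() and N >= 1):
        raise ValueError("N must be a positive integer number of nucleotides")
    return float(_RH_COEFF_M * N ** _RH_EXPONENT * 1e9)


def hydrodynamic_radius_bounds(N: int) -> tuple[float, float]:
    """1-sigma lower/upper R_h (nm) propagating the power-law coefficient
    and exponent uncertainties."""
    central = hydrodynamic_radius(N)
    rel = np.hypot(_RH_COEFF_SD / _RH_COEFF_M, _RH_EXPONENT_SD * np.log(N))
    return float(central * (1 - rel)), float(central * (1 + rel))


def viscosity(D: float, N: int, T: float = 298.15) -> ViscosityResult:
    """Stokes-Einstein viscosity estimate (mPa·s) from a measured D.

    D is in µm²/s; the RNA length N sets R_h through the power law; T
    defaults to the 25 °C assay temperature.
    """
    if not D > 0 or not T > 0:
        raise ValueError("D and T must be strictly positive")
    R_h_m = hydrodynamic_radius(N) * 1e-9
    eta_pa_s = BOLTZMANN_J_PER_K * T / (6.0 * np.pi * R_h_m * (D * 1e-12))
    return ViscosityResult(
        eta=float(eta_pa_s * 1e3), R_h=hydrodynamic_radius(N),
        T=float(T), D=float(D), N=int(N),
    )
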