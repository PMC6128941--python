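"""Single-turnover ribozyme cleavage kinetics.

Normalised product-formation traces I(t) are modelled as exponential
approaches to a plateau of 1:

    mono:  I(t) = 1 - exp(-(t - t0)/tau)
    bi:    I(t) = 1 - [A1 exp(-(t - t0)/tau1) + (1 - A1) exp(-(t - t0)/tau2)]

with dead time t0 fixed (measured separately, not fitted) and rate
constants k_i = 1/tau_i.  Gel band timecourses are fitted globally with a
shared time constant for the cleaved and uncleaved channels; the ratio of
the fitted intensity spans gives the FRET-effect factor used to correct
uncleaved-band intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "GelTimecourse",
    "MonoFit",
    "BiexpFit",
    "GelFitResult",
    "ModelSelection",
    "FitError",
    "background_subtract",
    "normalize_to_endpoint",
    "fit_monoexponential",
    "fit_biexponential",
    "select_model",
    "fit_gel_timecourse",
    "gel_cleaved_fraction",
    "mono_model",
    "biexp_model",
]

_TAU_LO, _TAU_HI = 1e-6, 1e8  # minutes; generous bounds for tau search


class FitError(RuntimeError):
    """Raised when a fit cannot be set up (too few points, bad input)."""


@dataclass
class KineticTrace:
    """Time-resolved fluorescence trace with condition metadata.

    times are minutes, strictly increasing; t0 is the dead time between
    reaction start and the first measurement.
    """

    times: np.ndarray
    intensities: np.ndarray
    condition: str = "buffer"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.t0 < 0:
            raise ValueError("dead time t0 must be >= 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class GelTimecourse:
    """Cleaved / uncleaved band-intensity timecourse (a.u., times in min)."""

    times: np.ndarray
    I_cleaved: np.ndarray
    I_uncleaved: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.I_cleaved = np.asarray(self.I_cleaved, dtype=float)
        self.I_uncleaved = np.asarray(self.I_uncleaved, dtype=float)
        if not (self.times.shape == self.I_cleaved.shape == self.I_uncleaved.shape):
            raise ValueError("channels must have equal length")
        if np.any(self.I_cleaved < 0) or np.any(self.I_uncleaved < 0):
            raise ValueError("band intensities must be nonnegative")


@dataclass(frozen=True)
class MonoFit:
    tau: float            # min
    k0: float             # 1/min, = 1/tau
    sse: float
    n_points: int
    converged: bool = True


@dataclass(frozen=True)
class BiexpFit:
    tau1: float           # min, fast (tau1 < tau2)
    tau2: float
    A1: float             # fast-phase amplitude, in [0, 1]
    k1: float             # 1/min
    k2: float
    sse: float
    n_points: int
    converged: bool = True


@dataclass(frozen=True)
class GelFitResult:
    tau: float
    k0: float
    C: float
    Imax_cleaved: float
    Imax_uncleaved: float
    fret_effect: float    # cleaved span / uncleaved span
    sse: float
    converged: bool = True


@dataclass(frozen=True)
class ModelSelection:
    preferred: str        # "mono" | "bi"
    f_statistic: float
    p_value: float
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# model functions

def mono_model(t: np.ndarray, tau: float, t0: float = 0.0) -> np.ndarray:
    return 1.0 - np.exp(-(np.asarray(t, dtype=float) - t0) / tau)


def biexp_model(
    t: np.ndarray, tau1: float, tau2: float, A1: float, t0: float = 0.0
) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return 1.0 - (
        A1 * np.exp(-(t - t0) / tau1) + (1.0 - A1) * np.exp(-(t - t0) / tau2)
    )


# ---------------------------------------------------------------------------
# trace preprocessing

def background_subtract(sample: KineticTrace, control: KineticTrace) -> KineticTrace:
    """Subtract a background trace (e.g. the inactive-ribozyme control).

    The control is linearly interpolated onto the sample grid when the grids
    differ.  Raises if the time ranges do not overlap.
    """
    if control.times[-1] < sample.times[0] or sample.times[-1] < control.times[0]:
        raise ValueError("sample and control time ranges are disjoint")
    bg = np.interp(sample.times, control.times, control.intensities)
    return replace(sample, intensities=sample.intensities - bg)


def normalize_to_endpoint(
    trace: KineticTrace, cleaved_fraction: float, at_time: float
) -> KineticTrace:
    """Rescale a trace so its value at ``at_time`` equals the gel-measured
    cleaved fraction.

    A single multiplicative factor is applied, anchoring the fluorescence
    scale to the fraction of substrate cleaved at that time.
    """
    if not 0.0 < cleaved_fraction <= 1.0:
        raise ValueError("cleaved_fraction must be in (0, 1]")
    if not trace.times[0] <= at_time <= trace.times[-1]:
        raise ValueError("at_time lies outside the trace time range")
    anchor = float(np.interp(at_time, trace.times, trace.intensities))
    if anchor == 0.0:
        raise ValueError("trace value at the anchor time is zero; cannot scale")
    return replace(trace, intensities=trace.intensities * (cleaved_fraction / anchor))


# ---------------------------------------------------------------------------
# exponential fits

def _multistart_least_squares(residual, starts, bounds):
    """Run bounded least squares from several starts; return the best result."""
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual, x0, bounds=bounds, method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def _tau_starts(times: np.ndarray, n: int = 8) -> np.ndarray:
    lo = max(times[times > 0].min() if np.any(times > 0) else 1e-2, 1e-3) / 3.0
    hi = max(times[-1] * 3.0, lo * 10)
    return np.geomspace(lo, hi, n)


def fit_monoexponential(trace: KineticTrace) -> MonoFit:
    """Least-squares fit of the single-exponential model; k0 = 1/tau.

    The dead time is taken from the trace and held fixed.  Multi-start over
    log-spaced tau initial values guards against local minima.
    """
    if len(trace) < 4:
        raise FitError("mono-exponential fit needs at least 4 points")
    t, y, t0 = trace.times, trace.intensities, trace.t0

    def residual(p):
        return mono_model(t, p[0], t0) - y

    best = _multistart_least_squares(
        residual, [[s] for s in _tau_starts(t)], ([_TAU_LO], [_TAU_HI])
    )
    if best is None:
        return MonoFit(np.nan, np.nan, np.inf, len(trace), converged=False)
    tau = float(best.x[0])
    return MonoFit(tau, 1.0 / tau, float(2 * best.cost), len(trace),
                   converged=bool(best.success))


def fit_biexponential(trace: KineticTrace) -> BiexpFit:
    """Least-squares fit of the bi-exponential model with tau1 < tau2.

    A1 is constrained to [0, 1] by bounded optimisation; the ordering
    tau1 < tau2 is enforced by relabelling after the fit so the reported
    k1 is always the faster rate.
    """
    if len(trace) < 6:
        raise FitError("bi-exponential fit needs at least 6 points")
    t, y, t0 = trace.times, trace.intensities, trace.t0

    def residual(p):
        return biexp_model(t, p[0], p[1], p[2], t0) - y

    taus = _tau_starts(t, 6)
    starts = []
    for i, ta in enumerate(taus):
        for tb in taus[i + 1:]:
            starts.append([ta, tb, 0.5])
    best = _multistart_least_squares(
        residual, starts, ([_TAU_LO, _TAU_LO, 0.0], [_TAU_HI, _TAU_HI, 1.0])
    )
    if best is None:
        return BiexpFit(*[np.nan] * 5, np.inf, len(trace), converged=False)
    tau1, tau2, A1 = map(float, best.x)
    if tau1 > tau2:
        tau1, tau2, A1 = tau2, tau1, 1.0 - A1
    return BiexpFit(
        tau1, tau2, A1, 1.0 / tau1, 1.0 / tau2,
        float(2 * best.cost), len(trace), converged=bool(best.success),
    )


def select_model(mono: MonoFit, bi: BiexpFit, alpha: float = 0.05) -> ModelSelection:
    """Choose between the nested mono and bi models by an extra-sum-of-squares
    F-test.

    The bi model adds two parameters (second time constant and amplitude
    split).  The bi model is preferred only when its residual reduction is
    significant at level ``alpha``.
    """
    if mono.n_points != bi.n_points:
        raise ValueError("fits compare different traces (n_points differ)")
    n = mono.n_points
    df_extra, df_bi = 2, n - 3
    if df_bi <= 0:
        raise ValueError("too few points for model comparison")
    if not (bi.sse < mono.sse):
        return ModelSelection("mono", 0.0, 1.0, alpha)
    if bi.sse == 0.0:
        return ModelSelection("bi", np.inf, 0.0, alpha)
    f_stat = ((mono.sse - bi.sse) / df_extra) / (bi.sse / df_bi)
    p = float(stats.f.sf(f_stat, df_extra, df_bi))
    return ModelSelection("bi" if p < alpha else "mono", float(f_stat), p, alpha)


# ---------------------------------------------------------------------------
# gel timecourse

def _gel_linear_solve(tau: float, gel: GelTimecourse):
    """At fixed tau the gel model is linear in (C, cleaved span, uncleaved
    span); solve that subproblem exactly."""
    u = np.exp(-gel.times / tau)
    n = gel.times.size
    # cleaved   = C + a * (1 - u)      (a = Imax_cleaved)
    # uncleaved = C + s * u            (s = Imax_uncleaved - C)
    design = np.zeros((2 * n, 3))
    design[:n, 0] = 1.0
    design[:n, 1] = 1.0 - u
    design[n:, 0] = 1.0
    design[n:, 2] = u
    target = np.concatenate([gel.I_cleaved, gel.I_uncleaved])
    coeff, *_ = np.linalg.lstsq(design, target, rcond=None)
    sse = float(np.sum((design @ coeff - target) ** 2))
    return coeff, sse


def fit_gel_timecourse(gel: GelTimecourse) -> GelFitResult:
    """Global fit of cleaved and uncleaved band timecourses with shared tau.

    tau is profiled over a log grid and refined by bounded scalar
    minimisation; the intensity parameters are solved by linear least
    squares at each tau.  The FRET-effect factor is the ratio of the fitted
    cleaved span to the fitted uncleaved span.
    """
    if gel.times.size < 4:
        raise FitError("gel fit needs at least 4 time points per channel")
    grid = np.geomspace(
        max(np.min(np.diff(gel.times)) / 10.0, 1e-6), gel.times[-1] * 100.0, 400
    )
    sses = np.array([_gel_linear_solve(tau, gel)[1] for tau in grid])
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda logtau: _gel_linear_solve(np.exp(logtau), gel)[1],
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-14},
    )
    tau = float(np.exp(res.x))
    (C, span_cl, span_un), sse = _gel_linear_solve(tau, gel)
    if span_un == 0:
        raise FitError("uncleaved span fitted to zero; FRET effect undefined")
    return GelFitResult(
        tau=tau, k0=1.0 / tau, C=float(C),
        Imax_cleaved=float(span_cl), Imax_uncleaved=float(span_un + C),
        fret_effect=float(span_cl / span_un), sse=sse,
        converged=bool(res.success),
    )


def gel_cleaved_fraction(
    I_cleaved: float, I_uncleaved: float, fret_effect: float
) -> float:
    """Fraction cleaved from band intensities, correcting the uncleaved band
    by the FRET-effect factor (cleaved substrate fluoresces more)."""
    if I_cleaved < 0 or I_uncleaved < 0:
        raise ValueError("band intensities must be nonnegative")
    if I_cleaved == 0 and I_uncleaved == 0:
        raise ValueError("both band intensities are zero")
    if not fret_effect > 0:
        raise ValueError("fret_effect must be positive")
    return I_cleaved / (I_cleaved + fret_effect * I_uncleaved)
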