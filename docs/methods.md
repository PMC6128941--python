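# Methods

`ribodrop` analyses the quantitative experiments used to characterise
ribozyme catalysis inside membrane-free coacervate protocells: single-turnover
cleavage kinetics, FRAP-based mobility measurements, two-phase partitioning,
and RNA exchange between droplets along a capillary channel. This note
records the models, their assumptions, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Cleavage kinetics

Normalised product-formation traces are modelled as exponential approaches
to a plateau of 1:

- mono-exponential (aqueous buffer): `I(t) = 1 − exp(−(t−t0)/τ)`, rate
  `k0 = 1/τ`;
- bi-exponential (coacervate phase and microdroplets):
  `I(t) = 1 − [A1·exp(−(t−t0)/τ1) + (1−A1)·exp(−(t−t0)/τ2)]`,
  rates `k_i = 1/τ_i`, with the ordering `τ1 < τ2` (so `k1` is the fast
  phase) enforced by relabelling after the fit.

Assumptions: single-turnover conditions (ribozyme in excess, each substrate
cleaved at most once), so the plateau is fixed at 1 after normalisation and
only time constants and the amplitude split are free. The dead time `t0`
between mixing and the first measurement is a measured input, fixed at 0 in
presets, never fitted.

Preprocessing mirrors the experimental chain: the inactive-ribozyme control
trace is subtracted as background (linearly interpolated onto the sample
grid when grids differ), and the fluorescence scale is anchored by a single
multiplicative factor chosen so the trace equals the gel-measured cleaved
fraction at the anchor time. Because the normalisation is purely
multiplicative, fitted rate constants are invariant to the raw intensity
scale.

Gel band timecourses are fitted globally: cleaved
`I(t) = Imax_cl·(1−e^{−t/τ}) + C` and uncleaved
`I(t) = C + (Imax_unc − C)·e^{−t/τ}` share one `τ` and one offset `C`.
The FRET-effect factor — the cleaved/uncleaved quantum-yield ratio — is
defined as the ratio of the fitted intensity spans (cleaved span over
uncleaved span), one definition used everywhere; the packaged preset value
is 1.69. Band intensities are corrected with
`fraction = I_cl / (I_cl + 1.69·I_uncl)`, the uncleaved band being the
dimmer species.

Model choice between mono and bi is decided by an extra-sum-of-squares
F-test at α = 0.05 (the bi model adds two parameters). Residual inspection
is the traditional criterion here; the F-test is the reproducible surrogate
adopted by this package.

## Fitting numerics

All nonlinear fits use bounded least squares (`scipy.optimize.least_squares`,
trust-region reflective, tolerances 1e-14) with log-spaced multi-starts over
the time constants (8 starts for mono, all ordered pairs from a 6-point log
grid for bi); the best optimum is kept, and a non-converged fit is returned
flagged, never silently. `A1` is box-constrained to [0, 1]. The gel fit
exploits separability: at fixed τ the three intensity parameters solve a
linear least-squares problem exactly, so τ is profiled on a 400-point log
grid and refined by bounded scalar minimisation — this cannot be trapped by
intensity-parameter local minima. Tests verify the optimiser against an
exhaustive log-grid search oracle on small traces.

## FRAP

Recovery curves are normalised as
`(bleach − background) / (reference − background)`, divided additionally by
the whole-droplet intensity for whole-droplet bleaching, then scaled so the
pre-bleach mean is exactly 1. The recovery model is piecewise:
`I(t) = 1` before the bleach and `1 − A·exp(−(t−t_bleach)/τ)` after, with
bleach depth `A ∈ (0, 1]` and time constant `τ` fitted. The model forces
full recovery at long times; incomplete recovery in real data (e.g. an
immobile fraction) shows up as a fitted `A < ` bleach depth or as residual
structure, and the fitted plateau is reported rather than reconciled.

Spot-FRAP τ converts to a diffusion coefficient by the half-time
approximation `D = 0.88 r²/(4 ln2 · τ)` with `r` the bleach-spot radius
(`t_1/2 = τ·ln2` for the exponential fit); the logarithm is natural.
Whole-droplet τ is an exchange time between droplet and exterior, not a
lateral-diffusion time, and the API refuses to convert it.

Viscosity follows from Stokes–Einstein, `η = k_B·T/(6π·R_h·D)`, with the
RNA hydrodynamic radius modelled as the power law `R_h = 5×10⁻¹⁰·N^0.38 m`
for `N` nucleotides. Central coefficient values define point estimates; the
quoted power-law uncertainties (±0.28 on the coefficient prefactor, ±0.01
on the exponent) are available as an optional 1σ band. `T` defaults to
298.15 K (assays at 25 °C); `k_B = 1.380649×10⁻²³ J/K`. With the preset
`D = 1.0 µm²/s` and `N = 39` this gives η ≈ 108.6 mPa·s, and the substrate
pair (1.6 µm²/s, 12 nt) gives ≈ 106.2 mPa·s — consistent within ~2%, which
is why a single pooled viscosity is meaningful.

## Partitioning

With intensities proportional to per-phase RNA amounts, the fraction in a
phase is `F = I_phase/ΣI`, per-phase concentrations are
`c = F·c_ini·V_ini/V_phase`, and `K = c_coac/c_sup`. The experimental
sample-handling step (each separated phase topped back up to the initial
volume with RNA-free counterpart phase) is treated as measurement plumbing:
intensities already represent total per-phase amounts, so the equations
apply directly. `c_sup = 0` yields a flagged unbounded K rather than an
error. Inverting the same mass balance,
`c_coac·V_coac + c_sup·(V_total−V_coac) = c_total·V_total` with
`c_coac = K·c_sup`, predicts in-droplet concentrations when RNA-loaded
coacervate is dispersed in supernatant: the preset values (K = 9600, 1 µM,
1 µl in 50 µl) give 49.75 µM ribozyme and (K = 3000, 0.5 µM) 24.6 µM
substrate — an ~50-fold enrichment. These central-K predictions sit 0.3–1.2%
above the measured-fraction values of 49.6 and 24.3 µM; the gap is
documented and tolerated at 5% in tests.

## Channel transport simulator

The capillary-channel localisation experiment — ribozyme-loaded droplets at
one end (region 1), substrate-loaded droplets at the other (region 3),
empty droplets between (region 2) — is modelled minimally: well-mixed
droplets coupled to a 1-D dilute-phase concentration field. Each time step
applies, in order:

1. explicit conservative finite-difference diffusion of each dilute field
   (no-flux boundaries);
2. droplet↔local-cell exchange moving `dt·J` moles with
   `J = k_ex·V_d·(K·c_local − c_droplet)/K`, whose fixed point is the
   partition equilibrium `c_droplet = K·c_local`;
3. exact first-order substrate→product conversion at rate `k_cat` inside
   ribozyme-containing droplets.

The exchange rate is identified with the inverse whole-droplet FRAP time,
`k_ex = 1/τ_wd`, since that τ measures droplet↔exterior exchange. Under
this flux law a droplet drains into an empty environment on the timescale
`K/k_ex` — the equilibrium bias that retains high-K species — while `k_ex`
itself sets how fast a droplet depletes its local cell; the strong
K-ordering (9600 vs 3000 vs ~10³ for the short product) is what produces
ribozyme retention alongside substrate/product transfer.

Numerics: explicit Euler with guards `dt·max(rate) < 0.1` and the diffusive
CFL condition `dt ≤ 0.25·dx²/D`, chosen for transparency and testable
first-order convergence over implicit speed. All sub-steps are written as
pairwise transfers, so total moles per species are conserved to round-off
without cleavage (verified to ≤1e-9 relative over 10⁵ steps) and
substrate + product jointly with it. Droplets are attached to their nearest
grid cell and do not move, coalesce or ripen. Negative concentrations abort
the run with the offending step.

Scenario defaults (the packaged three-region configuration): channel
3000 µm, 60 cells, 10⁴ µm² cross-section; three 10-µm-radius droplets per
region; in-droplet loadings from the dispersion mass balance at 0.36 µM
total RNA; `k_cat` set to the microdroplet fast rate (4.4×10⁻²/min);
dilute-phase diffusion 150 µm²/s for the 12-/6-mers and 100 µm²/s for the
39-mer (aqueous-buffer scale); product exchange parameters K = 1000 and
τ_wd = 12 s, extrapolating the observed RNA-length trend since they are not
measured for this polymer system. A 500-minute run at dt = 1 s takes about
a second. No numeric onset delays are measured for the real experiment;
only the region ordering (onset 1 < 2 < 3) and ribozyme retention (<1%
reaching region-2 droplets) are treated as reproducible, and both hold in
the default scenario.

## Synthetic data

Generators produce exactly what the analysis consumes: mono/bi kinetic
traces, shared-τ gel band pairs, piecewise FRAP recoveries (spot τ derived
from D and r when requested), and two-phase intensity pairs implied by a
given K and the volumes. Noise is i.i.d. additive Gaussian on intensity
with a seeded generator — bit-reproducible, and σ = 0 reproduces the
closed forms to machine precision. Not emulated: heteroscedastic or
correlated noise, photophysics (acquisition bleaching, spectral crosstalk
beyond the scalar FRET factor), droplet size distributions, or raw images.
Passing recovery tests therefore demonstrate correctness of the fitting
chain under the stated noise model, not robustness to instrument
systematics.

Preset amplitude splits (`A1 = 0.5` for both coacervate conditions) and
dead times (`t0 = 0`) are free choices — the study reports neither — and
only affect round-trip consistency tests, which compare against the preset
itself. The bleach-spot radius defaults to 2 µm (a typical confocal spot);
only the τ↔D round trip depends on it.

## Statistical test conditions

Recovery suites use σ = 0.02 with 500-point traces over 100 seeds (median
relative error ≤5% required for mono, bi and FRAP fits). The bi-exponential
suite runs under the microdroplet condition (k1 = 4.4×10⁻², k2 = 2.3×10⁻³/min
over 0–900 min), where both phases are well sampled by the window; under the
bulk condition the slow phase (τ2 ≈ 6700 min against a 530-min window) is a
near-linear ramp and its rate is intrinsically weakly identified at this
noise level. Model selection is checked at σ = 0.01 with 100-point traces
and 100× separated rates; the F-test's nominal 5% false-positive rate means
~95/100 correct "mono" calls is the expected ceiling, and ≥95/100 is
required for both directions.

## Known limitations

- The bi-exponential model is phenomenological; it does not identify the
  mechanistic origin of biphasic kinetics (heterogeneous folding states,
  conformational equilibria).
- The FRAP model forces complete recovery; systems with a genuine immobile
  fraction need an explicit mobile-fraction parameter, deferred.
- The transport model is 1-D and droplet-static; it cannot represent
  droplet-resolved gradients, coalescence, or Mg²⁺/salt effects.
- Partition analysis assumes intensity strictly proportional to amount with
  identical quantum yield in both phases.
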