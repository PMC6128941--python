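# ribodrop

Analysis toolkit for ribozyme catalysis in membrane-free coacervate
protocells. Coacervate microdroplets — formed by liquid–liquid phase
separation of oppositely charged polymers such as carboxymethyl-dextran and
poly-L-lysine — concentrate RNA thousands-fold and are a candidate
compartment for an RNA-world protocell. `ribodrop` implements the
quantitative pipeline needed to characterise a hammerhead ribozyme and its
FRET substrate in that environment, for experimentalists working with
plate-reader FRET assays, gel timecourses, confocal FRAP and two-phase
partition measurements.

## What it computes

- **Cleavage kinetics** — background subtraction (inactive-mutant control),
  gel-endpoint normalisation, and least-squares fits of
  `I(t) = 1 − e^{−(t−t₀)/τ}` (buffer) or
  `I(t) = 1 − [A₁e^{−(t−t₀)/τ₁} + (1−A₁)e^{−(t−t₀)/τ₂}]` (coacervate),
  with rate constants `k = 1/τ` and mono-vs-bi model choice by an
  extra-sum-of-squares F-test. Gel band timecourses are fitted globally
  with a shared τ, also yielding the FRET-effect factor used to correct
  uncleaved-band intensities.
- **FRAP** — ROI normalisation and fits of
  `I(t) = 1 − A·e^{−(t−t_bleach)/τ}`; spot-mode τ converts to a diffusion
  coefficient via `D = 0.88 r²/(4 ln2·τ)`; viscosity follows from
  Stokes–Einstein `η = k_BT/(6πR_h D)` with `R_h = 5×10⁻¹⁰·N^{0.38}` m for
  an RNA of N nucleotides. Whole-droplet τ is reported as an exchange time
  and is never converted to D.
- **Partitioning** — phase fractions `F = I_phase/ΣI`, per-phase
  concentrations `c = F·c_ini·V_ini/V_phase`, partition coefficient
  `K = c_coac/c_sup`, and the inverse mass balance predicting in-droplet
  concentrations from K.
- **Channel transport** — a conservative 1-D compartment simulator of the
  capillary localisation experiment (droplet↔dilute exchange at
  `k_ex = 1/τ_wd`, partition-equilibrium flux, in-droplet cleavage),
  reporting per-droplet product traces and onset times.
- **Synthetic data** — seeded generators for every input above, with a
  packaged preset (`ribodrop.CMDEX_PLYS`) holding the study constants, so
  the whole chain is testable end to end without instrument data.

## Worked example

```python
import numpy as np
from ribodrop import synthetic, kinetics, frap, partition

# microdroplet cleavage kinetics (noiseless preset trace, 0-900 min)
trace = synthetic.preset_fret_trace("droplet")
fit = kinetics.fit_biexponential(trace)
print(f"k1 = {fit.k1:.4g}/min, k2 = {fit.k2:.4g}/min, A1 = {fit.A1:.3g}")

# whole-droplet FRAP: ribozyme exchange time
wd = synthetic.preset_frap_trace("ribozyme", "whole_droplet")
print(f"tau_wd = {frap.fit_recovery(wd).tau:.4g} s")

# spot FRAP -> diffusion -> viscosity
spot = synthetic.preset_frap_trace("ribozyme", "spot")
D = frap.diffusion_from_fit(frap.fit_recovery(spot), spot).D
eta = frap.viscosity(D, 39).eta
print(f"D = {D:.4g} um^2/s, eta = {eta:.4g} mPa.s")

# in-droplet concentration from the partition coefficient
c_coac, c_sup = partition.droplet_concentration_from_K(9600, 1.0, 1.0, 50.0)
print(f"c_coac = {c_coac:.4g} uM, c_sup = {c_sup:.4g} uM")
```

prints

```
k1 = 0.044/min, k2 = 0.0023/min, A1 = 0.5
tau_wd = 189 s
D = 1 um^2/s, eta = 108.6 mPa.s
c_coac = 49.75 uM, c_sup = 0.005182 uM
```

The fast microdroplet rate (4.4×10⁻²/min) sits between the buffer rate
(0.6/min) and the bulk-coacervate fast rate (1.0×10⁻²/min); the 189 s
exchange time and K = 9600 together explain why the 39-mer ribozyme stays
in its droplet while the 12-mer substrate (τ = 22 s, K = 3000) transfers;
and the mass balance shows a ~50-fold up-concentration of ribozyme inside
a microdroplet.

The same workflows run from the shell:

```
ribodrop generate --kind kinetics --condition buffer --out buffer.csv
ribodrop fit-kinetics --input buffer.csv --model auto --out results/
# -> model=mono, k0 = 0.6 1/min in results/fit_kinetics.csv
ribodrop simulate-channel --out channel/   # three-region transport run
```

All tables are comma-separated text with units in the column names
(`time_min`, `time_s`, `conc_uM`); results are written as JSON + CSV
records with units and provenance.

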