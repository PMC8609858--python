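# chlorosig

Can the chlorophyll fluorescence emitted by one phytoplankton cell act as a
light signal to its neighbours, and over what distances and cell densities
does that signal become appreciable?  `chlorosig` is a photon-budget
calculator for this question, built for marine photobiologists modelling
diatom blooms.  It combines:

* a **per-cell flux calibration** that converts a bulk laboratory
  measurement of chlorophyll fluorescence photon flux density (CFPFD) into
  the photon flux *u* emitted by a single cell,
* a **pairwise propagation model** for the flux density one cell receives
  from another,
* an attenuated **mean-field population model** with a closed form, and its
  inversion giving the radius that encloses any fraction of the total flux,
* a **discrete-cell Monte Carlo simulation** (homogeneous Poisson point
  process) that independently checks the mean-field integral,
* standard **PAM photophysiology** parameters (Fv/Fm, Y(II), NPQ, rETR) and
  the xanthophyll de-epoxidation state (DEPS),
* an **iron-stratified correlation analysis** of station-level chlorophyll
  content against normalized ISIP (iron-starvation-induced protein)
  expression shares, exercised on seeded synthetic station tables.

## The model

A spherical plastid of radius *r* emits fluorescence isotropically with
per-cell photon flux *u* (μmol photons·s⁻¹).  A receiver at centre distance
*R* intercepts the solid-angle fraction πr²/(4πR²) on the illuminated half
of its plastid surface (2πr²):

    CFPFD(R) = u · (πr² / 4πR²) / (2πr²) = u / (8πR²)

For a uniform population at number density *N* (cells·m⁻³), summing over
spherical shells with Beer–Lambert attenuation (diffuse attenuation
coefficient K_d, m⁻¹) gives the total received flux

    CFPF = ∫₀^∞ 4πR² · N · u · (πr²/4πR²) · e^(−K_d·R) dR = N·u·πr² / K_d

Truncating at R_max multiplies this by 1 − e^(−K_d·R_max), so the radius
enclosing a fraction *f* of the total is −ln(1−f)/K_d — independent of
cell density.  Defaults: r = 3 μm, K_d = 0.57 m⁻¹, u = 9.07×10⁻¹²
μmol photons·s⁻¹.

## Worked example

```python
from chlorosig import (OpticalParams, CalibrationMeasurement, PairwiseScene,
                       PopulationScene, calibrate_per_cell_flux, pairwise_cfpfd,
                       population_cfpfd, contribution_radius, PointProcessConfig,
                       simulate_received_flux)
from chlorosig.units import cells_per_ml_to_per_m3

meas = CalibrationMeasurement(measured_cfpfd=2.418e-2,          # μmol/m²/s at the cuvette face
                              cell_density_n=cells_per_ml_to_per_m3(1.6e6))
u = calibrate_per_cell_flux(meas)
params = OpticalParams(per_cell_flux_u=u)

print(f"per-cell flux u           = {u:.3e} umol photons/s")
print(f"CFPFD, touching cells     = {pairwise_cfpfd(PairwiseScene(6e-6, params)):.2e} umol/m2/s")
print(f"CFPFD at 100 um           = {pairwise_cfpfd(PairwiseScene(1e-4, params)):.2e} umol/m2/s")
print(f"bloom CFPFD at 1.6e12/m3  = {population_cfpfd(PopulationScene(1.6e12, params=params)):.2f} umol/m2/s")
print(f"99.9% contribution radius = {contribution_radius(params, 0.999):.2f} m")

cfg = PointProcessConfig(cell_density_n=1e8, outer_radius=20.0, seed=1, replicates=200)
res = simulate_received_flux(cfg, params, tail_radius=12.12)
print(f"Monte Carlo mean flux     = {res.mean_flux:.4e} +/- {res.se_flux:.1e} umol/s")
print(f"mean-field integral       = {res.oracle_flux:.4e} umol/s  (z = {res.z_score:+.2f})")
print(f"flux beyond 12.12 m       = {100*res.tail_fraction:.2f} %")
```

prints

```
per-cell flux u           = 9.068e-12 umol photons/s
CFPFD, touching cells     = 1.00e-02 umol/m2/s
CFPFD at 100 um           = 3.61e-05 umol/m2/s
bloom CFPFD at 1.6e12/m3  = 12.73 umol/m2/s
99.9% contribution radius = 12.12 m
Monte Carlo mean flux     = 4.4973e-14 +/- 4.4e-18 umol/s
mean-field integral       = 4.4978e-14 umol/s  (z = -1.17)
flux beyond 12.12 m       = 0.10 %
```

Reading the numbers: a 1 mL suspension at 1.6×10⁶ cells/mL measuring
2.418×10⁻² μmol/m²/s at one cuvette face implies each cell emits
~9.07×10⁻¹² μmol photons/s.  Two touching cells exchange ~0.01 μmol/m²/s,
four orders of magnitude below typical growth irradiance, and the signal
falls off as 1/R².  In a dense bloom the *population* flux density can
reach ~13 μmol/m²/s — a physiologically meaningful light level — and 99.9%
of it originates within 12.12 m of the receiving cell regardless of
density.  The discrete-cell simulation (200 replicates, 3.4×10¹² expected
cells in a 20 m shell) agrees with the mean-field integral within ~1
standard error.

A `chlorosig` command-line tool exposes the same operations
(`calibrate`, `pairwise`, `population`, `radius`, `scan`, `simulate`,
`spectrum`, `pam`, `stations`, `generate`); try
`chlorosig radius --fraction 0.999` or `chlorosig --help`.

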