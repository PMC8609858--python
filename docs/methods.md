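# Methods

## Scope and assumptions

`chlorosig` models chlorophyll fluorescence as isotropic point-source
emission from spherical plastids propagating through water with
Beer–Lambert attenuation.  There is no radiative-transfer treatment beyond
this (no scattering phase functions, no wavelength-dependent K_d, no
sea-surface irradiance), no cell–cell occlusion, and no time dynamics.
Those are deliberate non-goals: the package answers a photon-budget
question — how much fluorescence can a cell receive from its neighbours —
not a full ocean-optics one.

## Calibration geometry

The per-cell emitted flux *u* is anchored to a bulk measurement: the CFPFD
at one face of a 1 mL cuvette holding a suspension of known density.  The
sample is modelled as a cube observed through one face; with isotropic
emission, 1/6 of all emitted photons exit each face, so

    u = 6 · CFPFD_measured · V^(2/3) / (N · V)

This is the simplest geometry consistent with converting
2.418×10⁻² μmol·m⁻²·s⁻¹ at 1.6×10⁶ cells/mL into exactly
u = 9.07×10⁻¹² μmol photons·s⁻¹; the factor is configurable
(`CalibrationMeasurement.geometry_factor`) for other observation
geometries.  Self-absorption and scattering inside the cuvette are
neglected, which biases *u* low if the suspension is optically thick.

## Pairwise model

Received flux density between two cells is u·(πr²/4πR²)/(2πr²) = u/(8πR²):
the emitter's flux diluted over the sphere of radius R, intercepted by the
receiver's plastid cross-section πr², and normalized by the illuminated
half-surface 2πr².  Three conventions matter and are fixed as follows:

* "adjacent cells" means centre-to-centre distance R = 2r (6 μm at
  default r); scenes with R < 2r raise `GeometryError` (overlap) and the
  formula's R → 0 singularity is thereby unreachable;
* the solid-angle fraction uses the far-field approximation πr²/(4πR²)
  even at contact — no spherical-cap correction — because the model's
  printed anchor values (1.0×10⁻² at contact, 3.61×10⁻⁵ at 100 μm) are
  both reproduced only under this reading;
* no attenuation factor: e^(−K_d·R) differs from 1 by < 10⁻⁴ at any
  plausible intercellular distance.

## Population model

For a homogeneous population the per-shell contribution
4πR²·N·u·(πr²/4πR²)·e^(−K_d·R) reduces to N·u·πr²·e^(−K_d·R), giving the
closed form N·u·πr²/K_d over infinite space and the factor
1 − e^(−K_d·R_max) under truncation.  `population_cfpf_numeric` integrates
the reduced integrand with adaptive quadrature (`scipy.integrate.quad`,
absolute/relative tolerances 10⁻¹⁰/10⁻⁸, infinite limits handled by quad's
semi-infinite transform) and raises `NumericalError` when the error
estimate exceeds ten times the requested tolerance.  The flux density seen
by the focal cell divides by the same half-surface 2πr² as the pairwise
model; the plastid radius then cancels exactly (CFPFD = N·u/(2K_d)), a
property the tests assert at 10⁻¹² relative.

The contribution radius is computed analytically, −ln(1−f)/K_d, not by
root-finding; at f = 0.999 and K_d = 0.57 m⁻¹ it is 12.119 m (12.12 m to
four figures; a value of 12.10 m arises under some rounding conventions and
agrees within 0.2%).

## Discrete-cell Monte Carlo

The simulation realizes "evenly distributed cells" as a homogeneous Poisson
point process in a spherical shell [R_in, R_out] around the focal cell and
sums u·(πr²/4πR²)·e^(−K_d·R) over realized cells.  Design choices:

* **Radial-only sampling.**  The summand depends on distance only, so
  positions are reduced to radii with density ∝ R² (inverse-CDF via cube
  root); this is distribution-identical to sampling 3-D coordinates at a
  fraction of the cost.
* **Inner radius 6 μm** (= 2r) by default: a discrete sum, unlike the
  mean-field integral, diverges in probability as R_in → 0, so the overlap
  distance is the physically sensible cutoff.  Analytically the slice
  [0, 2r] carries ~3×10⁻⁶ of the total flux and the whole near field
  [2r, 1 mm] about 6×10⁻⁴, so the mean-field integral's lower limit of 0
  is harmless.
* **Stratified realization.**  At oceanic densities the expected count in
  an attenuation-length shell is ~10¹² cells, far beyond what can be
  materialized.  The shell is split into 64 log-spaced sub-shells — the
  restriction of a Poisson process to disjoint regions is again Poisson,
  so this is exact, not an approximation — and within any sub-shell whose
  realized count K exceeds `max_points` (default 10⁵), only M = max_points
  radii are sampled and the sub-shell sum is weighted by K/M.  The
  estimator remains unbiased; because 1/R² varies by only ~2× within a
  log-spaced sub-shell, the added variance is small, and the near-field
  sub-shells (tiny expected counts, violently varying summand) are always
  simulated exactly.  `sample_positions` remains a plain single-shell
  exact sampler and refuses scenes whose expected count exceeds the cap.
* **Seeding.**  One `numpy.random.Generator` seeded from the config drives
  counts and radii; results carry the seed and replicate count.

Default ensemble sizes used in the test suite — 200 replicates for the
dense-scene comparison, 100 for unbiasedness checks — give standard errors
around 10⁻⁴ relative, ample for a 3-standard-error agreement test.

## Spectral reduction

The measured CFPFD entering calibration is obtained from an emission
spectrum by trapezoidal integration over the chlorophyll fluorescence band,
default 670–700 nm (bracketing the 685 nm emission peak), after subtracting
a straight-line baseline through the band-edge intensities (clipping
negative residuals to zero).  The instrument's exact band and baseline are
rarely reported, so both are configurable; integration stays on the native
grid to avoid resampling artifacts.  Peak detection maximizes the
baseline-corrected intensity in a window, ties breaking toward the lower
wavelength, and flags spectra with no excess over the baseline as having no
distinct peak.

## PAM photophysiology

Fv/Fm = (Fm − F0)/Fm, Y(II) = (Fm′ − F)/Fm′, NPQ = (Fm − Fm′)/Fm′,
rETR = Y(II)·PAR·0.84·0.5, DEPS = Dtx/(Ddx + Dtx).  Two conventions are
worth noting.  The Y(II) denominator is the light-adapted Fm′; a
strict-literal mode (`y2(step, literal_fm=...)`) substitutes the dark Fm,
and the two coincide in darkness.  The rETR absorptance (0.84) and PSII
excitation fraction (0.5) are the conventional defaults — instrument-
specific factors differ, so rETR values are comparable only within one
protocol and the tests treat instrument-scale agreement as a magnitude
check, never an exact target.  All ratios are invariant under a common
rescaling of the fluorescence yields; type invariants (Fm ≥ F0 ≥ 0,
Fm′ ≥ F ≥ 0, PAR ≥ 0) are enforced at construction.

## Station correlations

Each ISIP gene is expressed as a percentage of the station's four-gene
ISIP total and then divided by the station's total diatom unigene
expression.  Because the unigene scaling is a per-station positive scalar
applied identically to all four genes, performing it before or after the
percentage step changes no within-bin Pearson r (verified by test); the
percentage-first order is used.  Iron bins are closed intervals (defaults
[1.24, 1.39], [0.98, 1.13], [0.13, 0.30], [0, 0.05] μmol·m⁻³); stations
outside every bin enter only the pooled correlation, which is reported
alongside the per-bin rows.  Pearson r uses the product-moment estimator
with two-sided p-values from the t distribution on n − 2 degrees of
freedom; bins with n < 3 or zero variance are flagged not computable.  No
multiple-testing correction is applied, matching the conventional
presentation of a four-bin stratification.  qRT-PCR relative expression
uses the standard 2^−ΔΔCt transform.

## Synthetic data

The generators produce every input the pipeline consumes, deterministic
under an integer seed.

* **Spectra**: a Gaussian fluorescence peak (centre 685 nm, σ = 10 nm) on
  a low-order polynomial background chosen gentle enough that the
  linear-endpoint baseline removes it almost exactly, keeping the analytic
  Gaussian band integral (returned alongside the spectrum) a clean oracle.
  Optional Gaussian noise; defaults are noise-free.
* **PAM traces**: Fm′(PAR) = Fm/(1 + k·PAR) (NPQ linear in PAR,
  k = 1.3×10⁻³ by default, giving NPQ ≈ 1 at PAR ≈ 800 — the scale seen
  in light-curve protocols) and Y(PAR) = (Fv/Fm)·e^(−PAR/300), so
  Fm ≥ Fm′ ≥ F ≥ 0 and the monotone quenching pattern hold by
  construction; a dark step reproduces F0 and Fm exactly.  Defaults
  F0 = 0.4, Fm = 1.0 give the Fv/Fm ≈ 0.6 typical of healthy diatoms.
* **Station tables**: chlorophyll is log-normal (median 1 mg·m⁻³, log-sd
  0.5); within each iron bin the focal gene's *normalized share* is built
  as loc + scale·(ρ·x̃ + √(1−ρ²)·ε) with x̃ the standardized chlorophyll,
  then inverted exactly through the share-normalization pipeline (the
  percentage is the target share times the station's unigene total, and
  the remaining three genes split the residual ISIP composition by a
  Dirichlet draw).  A linear blend is used rather than a nonlinear margin
  map because Pearson correlation of a linear blend equals ρ for *any*
  chlorophyll margin, and because it makes ρ = 1 with zero noise produce
  r = 1 exactly.  Two noise couplings are offered: `empirical` (default)
  orthogonalizes ε to chlorophyll within the sample, fixing the *sample*
  correlation to ρ exactly — the same construction as multivariate-normal
  generation with an empirical target covariance — while `population`
  leaves ε free so sample r fluctuates with the usual √((1−ρ²)²/(n−1))
  spread.  The default per-bin ρ (0.44, 0.84, 0.66, 0.30) follow the
  stratified correlations reported for survey-derived station tables,
  with the lowest-iron bin (unreported there) set to a moderate 0.30.

What the generators do **not** emulate: instrument noise spectra, real
metatranscriptome abundance distributions beyond positivity and skew,
spatial autocorrelation between stations, or chlorophyll–iron coupling
across bins.  Passing tests therefore demonstrate the correctness of the
computations and the recoverability of imposed statistical structure, not
the field values of the real survey data, whose correlations depend on the
external dataset.

## Numerical and interface choices

SI units internally (m, s, m⁻³, μmol photons); cells/mL and μm are
converted only at interface boundaries (`chlorosig.units`).  All CSVs are
comma-separated, dot-decimal UTF-8 with mandatory headers; `#` lines are
comments.  CLI outputs are written atomically (temp file + rename) and
logging goes to stderr only, so identical configuration and seed yield
byte-identical result files.  Degenerate inputs fail loudly: overlapping
cells (`GeometryError`), zero denominators (`UndefinedRatioError`),
non-monotone wavelength grids, duplicate station ids, zero-variance
correlation bins (flagged, not raised).

## Known limitations

* The calibration cube-face geometry is an idealization; real cuvette
  measurements include wall reflections and detector acceptance angles
  folded into the configurable geometry factor.
* The far-field solid-angle approximation overestimates the intercepted
  fraction slightly at contact distances (exact spherical-cap geometry
  would give a smaller value at R = 2r).
* K_d is a single scalar; in reality it varies with wavelength and water
  type, and the fluorescence band straddles a strong absorption feature of
  water.
* The stratified Monte Carlo is unbiased but its variance estimate relies
  on replicate spread; for very small replicate counts the standard error
  itself is noisy.
* The station analysis reproduces the *procedure*; the published
  correlation values belong to the external survey data and are not
  desk-reproducible.
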