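"""Seeded synthetic-data generators for every pipeline input.

Three generators emulate the structures the analysis consumes:

* :func:`make_spectrum` — an emission spectrum with a Gaussian chlorophyll
  fluorescence peak (default centre 685 nm) on a smooth low-order
  polynomial background, with the analytic band integral returned alongside
  for use as an oracle.
* :func:`make_pam_trace` — a PAM light curve with saturating-pulse
  structure ``Fm ≥ Fm′(PAR) ≥ F(PAR) ≥ 0``, monotone quenching in PAR.
* :func:`make_station_table` — per-station chlorophyll, dissolved iron,
  ISIP expressions and diatom-unigene totals, with a configurable Pearson
  correlation between chlorophyll and the normalized ISIP share inside each
  iron bin.

All generators are deterministic under a fixed integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError
from .photophys import PAMRecord, PAMStep
from .spectral import DEFAULT_BAND, EmissionSpectrum
from .stations import DEFAULT_IRON_BINS, ISIP_GENES, IronBins, validate_station_table

__all__ = [
    "SpectrumConfig",
    "SyntheticSpectrum",
    "make_spectrum",
    "gaussian_band_integral",
    "amplitude_for_band_integral",
    "PAMTraceConfig",
    "make_pam_trace",
    "StationTableConfig",
    "make_station_table",
]


# --------------------------------------------------------------------------
# Emission spectra


@dataclass(frozen=True)
class SpectrumConfig:
    """Parameters of the synthetic emission spectrum.

    The peak is Gaussian with amplitude ``peak_amplitude`` (spectral photon
    flux density per nm at the maximum), centre ``peak_centre_nm`` and
    standard deviation ``peak_sigma_nm``; the background is the gentle
    quadratic ``b0 + b1·(λ−λ0) + b2·(λ−λ0)²`` (λ0 = grid midpoint), chosen
    smooth so that linear-endpoint baseline removal is nearly exact.
    """

    seed: int
    peak_amplitude: float = 1.0e-3
    peak_centre_nm: float = 685.0
    peak_sigma_nm: float = 10.0
    grid_start_nm: float = 400.0
    grid_stop_nm: float = 750.0
    grid_step_nm: float = 0.5
    background: tuple[float, float, float] = (5.0e-4, -1.0e-6, 2.0e-9)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_sigma_nm <= 0:
            raise InvalidInputError("peak_sigma_nm must be strictly positive")
        if self.grid_step_nm <= 0 or self.grid_stop_nm <= self.grid_start_nm:
            raise InvalidInputError("invalid wavelength grid")
        if self.peak_amplitude < 0 or self.noise_sd < 0:
            raise InvalidInputError("peak_amplitude and noise_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticSpectrum:
    """A generated spectrum plus its analytic band-integral oracle."""

    spectrum: EmissionSpectrum
    band: tuple[float, float]
    #: Exact integral of the baseline-corrected Gaussian peak over ``band``.
    analytic_band_integral: float
    config: SpectrumConfig = field(repr=False, default=None)


def gaussian_band_integral(
    amplitude: float,
    centre: float,
    sigma: float,
    band: tuple[float, float] = DEFAULT_BAND,
    baseline: str = "linear",
) -> float:
    """Exact band integral of a Gaussian peak after baseline correction.

    For ``baseline="linear"`` the straight line through the Gaussian's
    values at the band edges is subtracted (any linear background cancels
    with it); for ``"none"`` the raw Gaussian integral over the band.
    """
    lo, hi = band
    gauss = lambda x: amplitude * math.exp(-0.5 * ((x - centre) / sigma) ** 2)
    z = lambda x: (x - centre) / sigma
    raw = amplitude * sigma * math.sqrt(2.0 * math.pi) * (
        stats.norm.cdf(z(hi)) - stats.norm.cdf(z(lo))
    )
    if baseline == "none":
        return raw
    chord = 0.5 * (gauss(lo) + gauss(hi)) * (hi - lo)
    return raw - chord


def amplitude_for_band_integral(
    target: float,
    centre: float = 685.0,
    sigma: float = 10.0,
    band: tuple[float, float] = DEFAULT_BAND,
    baseline: str = "linear",
) -> float:
    """Amplitude giving a requested baseline-corrected band integral.

    The band integral is linear in the amplitude, so this is a single
    division; use it to build a spectrum whose measured CFPFD equals a
    target value (e.g. the 2.418×10⁻² μmol·m⁻²·s⁻¹ reference measurement).
    """
    per_unit = gaussian_band_integral(1.0, centre, sigma, band, baseline)
    if per_unit <= 0:
        raise InvalidInputError("band does not capture the peak; per-unit integral <= 0")
    return target / per_unit


def make_spectrum(cfg: SpectrumConfig, band: tuple[float, float] = DEFAULT_BAND) -> SyntheticSpectrum:
    """Generate a synthetic emission spectrum.

    Returns the spectrum together with the analytic (noise-free,
    linear-baseline) band integral of the peak for oracle use.
    """
    rng = np.random.default_rng(cfg.seed)
    wl = np.arange(cfg.grid_start_nm, cfg.grid_stop_nm + 0.5 * cfg.grid_step_nm, cfg.grid_step_nm)
    mid = 0.5 * (wl[0] + wl[-1])
    b0, b1, b2 = cfg.background
    background = b0 + b1 * (wl - mid) + b2 * (wl - mid) ** 2
    peak = cfg.peak_amplitude * np.exp(-0.5 * ((wl - cfg.peak_centre_nm) / cfg.peak_sigma_nm) ** 2)
    intensity = background + peak
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, wl.size)
    intensity = np.clip(intensity, 0.0, None)
    analytic = gaussian_band_integral(
        cfg.peak_amplitude, cfg.peak_centre_nm, cfg.peak_sigma_nm, band, "linear"
    )
    return SyntheticSpectrum(
        spectrum=EmissionSpectrum(wl, intensity),
        band=band,
        analytic_band_integral=analytic,
        config=cfg,
    )


# --------------------------------------------------------------------------
# PAM traces


@dataclass(frozen=True)
class PAMTraceConfig:
    """Parameters of the synthetic PAM light curve.

    Quenching model: ``Fm′(PAR) = Fm/(1 + npq_slope·PAR)`` (so NPQ grows
    linearly with PAR) and effective yield ``Y(PAR) = (Fv/Fm)·e^(−PAR/par_scale)``
    (strictly decreasing); the real-time yield is ``F = Fm′·(1 − Y)``.
    A dark step (PAR = 0) reproduces ``Fm′ = Fm`` and ``F = F0`` exactly.
    """

    seed: int
    f0: float = 0.4
    fm: float = 1.0
    par_steps: tuple[float, ...] = (0.0, 21.0, 56.0, 111.0, 186.0, 336.0, 531.0, 801.0)
    npq_slope: float = 1.3e-3
    par_scale: float = 300.0

    def __post_init__(self) -> None:
        if not 0 <= self.f0 <= self.fm:
            raise InvalidInputError("need Fm >= F0 >= 0")
        if self.npq_slope < 0:
            raise InvalidInputError("npq_slope must be non-negative (yields would go negative)")
        if self.par_scale <= 0:
            raise InvalidInputError("par_scale must be strictly positive")
        if any(p < 0 for p in self.par_steps):
            raise InvalidInputError("PAR steps must be non-negative")


def make_pam_trace(cfg: PAMTraceConfig) -> PAMRecord:
    """Generate a PAM record satisfying ``Fm ≥ Fm′ ≥ F ≥ 0`` by construction."""
    fv_fm = (cfg.fm - cfg.f0) / cfg.fm if cfg.fm > 0 else 0.0
    steps = []
    for par in cfg.par_steps:
        fm_prime = cfg.fm / (1.0 + cfg.npq_slope * par)
        y = fv_fm * math.exp(-par / cfg.par_scale)
        steps.append(PAMStep(par=par, f=fm_prime * (1.0 - y), fm_prime=fm_prime))
    return PAMRecord(f0=cfg.f0, fm=cfg.fm, steps=tuple(steps))


# --------------------------------------------------------------------------
# Station tables


@dataclass(frozen=True)
class StationTableConfig:
    """Parameters of the synthetic station table.

    One block of ``n_per_bin`` stations is generated per iron bin, with the
    Pearson correlation between chlorophyll and the focal gene's normalized
    ISIP share set to ``rho_per_bin[k]`` inside bin ``k``.

    ``correlation="empirical"`` (default) imposes the *sample* correlation
    exactly: the noise component is orthogonalized to chlorophyll within the
    sample, the same construction as multivariate-normal generation with an
    empirical target covariance.  ``correlation="population"`` draws
    independent noise, so the sample r fluctuates around ρ with the usual
    sampling spread.

    Chlorophyll is log-normal (median ``chl_median`` mg·m⁻³, log-sd
    ``chl_sigma_log``); the default per-bin ρ follow the stratified
    correlations reported for the Tara-derived tables (0.44, 0.84, 0.66 for
    the three highest-iron bins; the lowest bin is unconstrained there and
    defaults to 0.30).
    """

    seed: int
    bins: IronBins = field(default_factory=IronBins)
    rho_per_bin: tuple[float, ...] = (0.44, 0.84, 0.66, 0.30)
    n_per_bin: int = 12
    gene: str = "isip2a"
    correlation: str = "empirical"
    chl_median: float = 1.0
    chl_sigma_log: float = 0.5
    share_loc: float = 0.5
    share_scale: float = 0.12
    unigene_median: float = 40.0
    unigene_sigma_log: float = 0.3
    isip_total_median: float = 100.0
    isip_total_sigma_log: float = 0.4

    def __post_init__(self) -> None:
        if len(self.rho_per_bin) != len(self.bins.intervals):
            raise InvalidInputError("rho_per_bin must have one entry per iron bin")
        if any(abs(r) > 1 for r in self.rho_per_bin):
            raise InvalidInputError("|rho| must not exceed 1")
        if self.n_per_bin < 3:
            raise InvalidInputError("n_per_bin must be at least 3")
        if self.gene not in ISIP_GENES:
            raise InvalidInputError(f"gene must be one of {ISIP_GENES}")
        if self.correlation not in ("empirical", "population"):
            raise InvalidInputError("correlation must be 'empirical' or 'population'")
        for name in ("chl_median", "share_scale", "unigene_median", "isip_total_median"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be strictly positive")


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise InvalidInputError("degenerate sample: zero variance")
    return (v - v.mean()) / sd


def _correlated_latent(rng: np.random.Generator, x: np.ndarray, rho: float, mode: str) -> np.ndarray:
    """Latent variable with Pearson correlation rho against x.

    A linear blend ``ρ·x̃ + √(1−ρ²)·ε`` of the standardized x with noise; in
    "empirical" mode ε is orthogonalized to x̃ and standardized within the
    sample, which makes the sample correlation exactly ρ.
    """
    xs = _standardize(x)
    eps = rng.standard_normal(x.size)
    if mode == "empirical":
        eps = eps - eps.mean()
        eps = eps - (eps @ xs) / (xs @ xs) * xs
        eps = _standardize(eps)
    return rho * xs + math.sqrt(1.0 - rho * rho) * eps


def make_station_table(cfg: StationTableConfig) -> pd.DataFrame:
    """Generate a station table with bin-wise correlation structure.

    Inside each iron bin the focal gene's normalized ISIP share (percentage
    of the four-gene total divided by the diatom-unigene total) carries the
    configured Pearson ρ against chlorophyll; the inversion is exact, so
    running :func:`chlorosig.stations.stratified_pearson` on the output
    recovers the latent construction.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    counter = 0
    for (lo, hi), rho in zip(cfg.bins.intervals, cfg.rho_per_bin):
        n = cfg.n_per_bin
        chl = cfg.chl_median * np.exp(rng.normal(0.0, cfg.chl_sigma_log, n))
        latent = _correlated_latent(rng, chl, rho, cfg.correlation)
        share_norm = cfg.share_loc + cfg.share_scale * latent  # target normalized share
        unigene = cfg.unigene_median * np.exp(rng.normal(0.0, cfg.unigene_sigma_log, n))
        pct = share_norm * unigene  # focal gene's percentage of the ISIP total
        if (pct <= 0).any() or (pct >= 100).any():
            warnings.warn(
                "clipping focal-gene percentages to (0, 100); the realized "
                "correlation departs slightly from the target",
                stacklevel=2,
            )
            pct = np.clip(pct, 1e-6, 100.0 - 1e-6)
        frac = pct / 100.0
        isip_total = cfg.isip_total_median * np.exp(rng.normal(0.0, cfg.isip_total_sigma_log, n))
        others = [g for g in ISIP_GENES if g != cfg.gene]
        other_w = rng.dirichlet(np.ones(3), size=n) * (1.0 - frac)[:, None]
        cols = {cfg.gene: frac * isip_total}
        for j, g in enumerate(others):
            cols[g] = other_w[:, j] * isip_total
        frames.append(
            pd.DataFrame(
                {
                    "station_id": [f"S{counter + i:03d}" for i in range(n)],
                    "chlorophyll": chl,
                    "iron": rng.uniform(lo, hi, n) if hi > lo else np.full(n, lo),
                    **{g: cols[g] for g in ISIP_GENES},
                    "diatom_unigene_total": unigene,
                }
            )
        )
        counter += n
    table = pd.concat(frames, ignore_index=True)
    return validate_station_table(table)
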