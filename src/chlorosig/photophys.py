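"""PAM fluorometry parameters and xanthophyll-cycle de-epoxidation state.

Standard pulse-amplitude-modulated (PAM) fluorescence quantities for
photosystem II:

* ``Fv/Fm = (Fm − F0)/Fm`` — maximum quantum yield, dark-adapted.
* ``Y(II) = (Fm′ − F)/Fm′`` — effective quantum yield under illumination,
  with the light-adapted maximal yield Fm′ as denominator (a strict-literal
  mode with the dark Fm is available; the two coincide in darkness).
* ``NPQ = (Fm − Fm′)/Fm′`` — non-photochemical quenching.
* ``rETR = Y(II) × PAR × absorption × PSII-fraction`` — relative electron
  transport rate; the instrument factors default to the conventional
  0.84 × 0.5 and should be overridden when known.

Pigments: ``DEPS = Dtx/(Ddx + Dtx)``, the de-epoxidation state of the
diadinoxanthin (Ddx) / diatoxanthin (Dtx) cycle.

All fluorescence ratios are unit-free: rescaling every yield by a common
factor leaves them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import InvalidInputError, UndefinedRatioError

__all__ = [
    "PAMStep",
    "PAMRecord",
    "PigmentRecord",
    "fv_over_fm",
    "y2",
    "npq",
    "retr",
    "deps",
    "light_curve_table",
    "read_pam_csv",
    "write_pam_csv",
]


@dataclass(frozen=True)
class PAMStep:
    """One light step: actinic PAR, real-time yield F, light-adapted Fm′."""

    par: float
    f: float
    fm_prime: float

    def __post_init__(self) -> None:
        if self.par < 0:
            raise InvalidInputError("PAR must be non-negative")
        if not 0 <= self.f <= self.fm_prime:
            raise InvalidInputError("need Fm' >= F >= 0 at every light step")


@dataclass(frozen=True)
class PAMRecord:
    """A dark-adapted measurement (F0, Fm) plus a light curve."""

    f0: float
    fm: float
    steps: tuple[PAMStep, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.f0 <= self.fm:
            raise InvalidInputError("need Fm >= F0 >= 0")
        object.__setattr__(self, "steps", tuple(self.steps))


@dataclass(frozen=True)
class PigmentRecord:
    """Pigment concentrations, mg per g dry weight."""

    chl_a: float
    ddx: float
    dtx: float

    def __post_init__(self) -> None:
        if min(self.chl_a, self.ddx, self.dtx) < 0:
            raise InvalidInputError("pigment concentrations must be non-negative")


def fv_over_fm(rec: PAMRecord) -> float:
    """Maximum PSII quantum yield, ``(Fm − F0)/Fm`` ∈ [0, 1]."""
    if rec.fm == 0:
        raise UndefinedRatioError("Fv/Fm undefined when Fm = 0")
    return (rec.fm - rec.f0) / rec.fm


def y2(step: PAMStep, *, literal_fm: float | None = None) -> float:
    """Effective PSII quantum yield under illumination.

    ``(Fm′ − F)/Fm′`` by default.  ``literal_fm`` substitutes the dark Fm
    as denominator (the strict-literal reading); both coincide in the dark
    where Fm′ = Fm.
    """
    denom = step.fm_prime if literal_fm is None else literal_fm
    if denom == 0:
        raise UndefinedRatioError("Y(II) undefined with a zero maximal yield")
    return (denom - step.f) / denom


def npq(rec: PAMRecord, step: PAMStep) -> float:
    """Non-photochemical quenching, ``(Fm − Fm′)/Fm′`` (≥ 0 when Fm ≥ Fm′)."""
    if step.fm_prime == 0:
        raise UndefinedRatioError("NPQ undefined when Fm' = 0")
    return (rec.fm - step.fm_prime) / step.fm_prime


def retr(step: PAMStep, absorption_factor: float = 0.84, distribution_factor: float = 0.5) -> float:
    """Relative electron transport rate, μmol electrons·m⁻²·s⁻¹.

    ``Y(II) × PAR × absorption_factor × distribution_factor``; the defaults
    are the conventional leaf absorptance 0.84 and equal PSII/PSI excitation
    split 0.5 — relative numbers only, unless instrument factors are known.
    """
    for name, val in (("absorption_factor", absorption_factor), ("distribution_factor", distribution_factor)):
        if not 0 < val <= 1:
            raise InvalidInputError(f"{name} must lie in (0, 1]")
    return y2(step) * step.par * absorption_factor * distribution_factor


def deps(rec: PigmentRecord) -> float:
    """De-epoxidation state of the Ddx cycle: ``Dtx/(Ddx + Dtx)`` ∈ [0, 1]."""
    pool = rec.ddx + rec.dtx
    if pool == 0:
        raise UndefinedRatioError("DEPS undefined when Ddx + Dtx = 0")
    return rec.dtx / pool


def light_curve_table(rec: PAMRecord, **retr_kwargs) -> pd.DataFrame:
    """Per-step parameter table: PAR, F, Fm′, Y(II), NPQ, rETR."""
    rows = [
        {
            "par": s.par,
            "f": s.f,
            "fm_prime": s.fm_prime,
            "y2": y2(s),
            "npq": npq(rec, s),
            "retr": retr(s, **retr_kwargs),
        }
        for s in rec.steps
    ]
    return pd.DataFrame(rows, columns=["par", "f", "fm_prime", "y2", "npq", "retr"])


def read_pam_csv(path: str | Path) -> PAMRecord:
    """Read a PAM trace CSV.

    Format: leading comment lines ``# F0 = <x>`` and ``# Fm = <x>`` carry the
    dark-adapted yields; then a header row ``par,f,fm_prime`` and one row per
    light step.
    """
    f0 = fm = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("#").partition("=")
            key = key.strip().lower()
            if key == "f0":
                f0 = float(value)
            elif key == "fm":
                fm = float(value)
    if f0 is None or fm is None:
        raise InvalidInputError("PAM CSV must carry '# F0 = ...' and '# Fm = ...' header lines")
    df = pd.read_csv(path, comment="#")
    if not {"par", "f", "fm_prime"}.issubset(df.columns):
        raise InvalidInputError("PAM CSV must have columns par, f, fm_prime")
    steps = [PAMStep(r.par, r.f, r.fm_prime) for r in df.itertuples()]
    return PAMRecord(f0=f0, fm=fm, steps=tuple(steps))


def write_pam_csv(rec: PAMRecord, path: str | Path) -> None:
    """Inverse of :func:`read_pam_csv`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# F0 = {rec.f0!r}\n# Fm = {rec.fm!r}\n")
        fh.write("par,f,fm_prime\n")
        for s in rec.steps:
            fh.write(f"{s.par!r},{s.f!r},{s.fm_prime!r}\n")
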