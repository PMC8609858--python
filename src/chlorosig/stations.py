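"""Station-level ISIP expression shares and iron-stratified correlations.

Iron-starvation-induced proteins (ISIP1, ISIP2a, ISIP2b, ISIP3) are markers
of diatom iron limitation.  Given a per-station table of chlorophyll
content, dissolved iron, the four ISIP transcript abundances and the total
diatom unigene expression, this module

1. expresses each ISIP as a percentage of the four-gene total and scales it
   by the station's total diatom unigene expression (the "normalized
   share"), and
2. computes the Pearson correlation between chlorophyll content and the
   normalized share within bins of dissolved-iron concentration, with
   two-sided p-values from the t distribution on n − 2 degrees of freedom.

Because the unigene scaling is a positive per-station scalar applied to all
four genes alike, the order of the two normalization steps does not change
any within-bin Pearson r; the percentage-then-scale order used here follows
the conventional presentation.

The real-data counterpart of these tables is the Tara Oceans diatom
metatranscriptome (ENA accession PRJEB6609) with environmental variables
from PANGAEA; see :func:`tara_adapter_stub`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError

__all__ = [
    "ISIP_GENES",
    "DEFAULT_IRON_BINS",
    "IronBins",
    "validate_station_table",
    "read_station_csv",
    "isip_share",
    "stratified_pearson",
    "StratifiedPearsonResult",
    "relative_expression_ddct",
]

ISIP_GENES = ("isip1", "isip2a", "isip2b", "isip3")

REQUIRED_COLUMNS = ("station_id", "chlorophyll", "iron", *ISIP_GENES, "diatom_unigene_total")

#: Default dissolved-iron bins, μmol·m⁻³ (closed intervals, high to low iron).
DEFAULT_IRON_BINS = ((1.24, 1.39), (0.98, 1.13), (0.13, 0.30), (0.0, 0.05))


@dataclass(frozen=True)
class IronBins:
    """Ordered, non-overlapping closed iron-concentration intervals (μmol·m⁻³)."""

    intervals: tuple[tuple[float, float], ...] = DEFAULT_IRON_BINS

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for lo, hi in ivs:
            if lo > hi:
                raise InvalidInputError(f"iron bin [{lo}, {hi}] has lower > upper")
        by_lo = sorted(ivs)
        for (_, hi1), (lo2, _) in zip(by_lo, by_lo[1:]):
            if lo2 < hi1:
                raise InvalidInputError("iron bins must not overlap")

    def assign(self, iron: pd.Series) -> pd.Series:
        """Bin index per station (−1 when outside every bin); edges inclusive."""
        out = pd.Series(-1, index=iron.index, dtype=int)
        for k, (lo, hi) in enumerate(self.intervals):
            out[(iron >= lo) & (iron <= hi)] = k
        return out

    def label(self, k: int) -> str:
        lo, hi = self.intervals[k]
        return f"[{lo:g}, {hi:g}]"


def validate_station_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the station-table contract; returns the table unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"station table missing columns: {missing}")
    if table["station_id"].duplicated().any():
        raise InvalidInputError("duplicate station_id values")
    for col in ("chlorophyll", "iron", *ISIP_GENES):
        if (table[col] < 0).any():
            raise InvalidInputError(f"negative values in column {col!r}")
    if (table["diatom_unigene_total"] <= 0).any():
        raise InvalidInputError("diatom_unigene_total must be strictly positive")
    return table


def read_station_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a station table CSV ('#' comment lines skipped)."""
    return validate_station_table(pd.read_csv(path, comment="#"))


def isip_share(table: pd.DataFrame, gene: str | None = None) -> pd.DataFrame:
    """Normalized ISIP expression shares per station.

    Each gene is first expressed as a percentage of the four-gene ISIP total
    (``share_pct``, summing to 100 per station), then divided by the
    station's total diatom unigene expression (``share_norm``).  Stations
    whose four-gene sum is zero are excluded with a warning.

    Parameters
    ----------
    gene : str, optional
        Restrict the output to one of ``isip1, isip2a, isip2b, isip3``.

    Returns
    -------
    pandas.DataFrame
        Indexed like the (retained) input rows, with columns
        ``{gene}_share_pct`` and ``{gene}_share_norm``.
    """
    validate_station_table(table)
    genes = ISIP_GENES if gene is None else (gene,)
    for g in genes:
        if g not in ISIP_GENES:
            raise InvalidInputError(f"unknown ISIP gene {g!r}; expected one of {ISIP_GENES}")
    total = table[list(ISIP_GENES)].sum(axis=1)
    zero = total == 0
    if zero.any():
        excluded = table.loc[zero, "station_id"].tolist()
        warnings.warn(
            f"excluding stations with zero total ISIP expression: {excluded}",
            stacklevel=2,
        )
    kept = table.loc[~zero]
    out = pd.DataFrame(index=kept.index)
    for g in genes:
        pct = 100.0 * kept[g] / total[~zero]
        out[f"{g}_share_pct"] = pct
        out[f"{g}_share_norm"] = pct / kept["diatom_unigene_total"]
    return out


@dataclass(frozen=True)
class StratifiedPearsonResult:
    """Per-bin Pearson correlations with the pooled (all-station) row.

    ``table`` columns: ``bin`` (interval label, plus ``pooled`` and
    ``unbinned``), ``n``, ``r``, ``p``, ``computable``.
    """

    table: pd.DataFrame
    x: str
    y: str
    bins: IronBins = field(repr=False, default_factory=IronBins)

    def summary(self) -> str:
        lines = [f"Pearson correlation of {self.y} vs {self.x}, stratified by iron bin"]
        for row in self.table.itertuples(index=False):
            if row.computable:
                lines.append(f"  {row.bin:>14}  n={row.n:<3d}  r={row.r:+.3f}  p={row.p:.4g}")
            else:
                lines.append(f"  {row.bin:>14}  n={row.n:<3d}  not computable")
        return "\n".join(lines)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (np.nan, np.nan, False)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p), True)


def stratified_pearson(
    table: pd.DataFrame,
    bins: IronBins | None = None,
    x: str = "chlorophyll",
    gene: str = "isip2a",
    y: str | None = None,
) -> StratifiedPearsonResult:
    """Iron-bin-stratified Pearson correlation of chlorophyll vs ISIP share.

    For each iron bin, correlates column ``x`` against the normalized share
    of ``gene`` (or an explicit column ``y``) over the stations falling in
    the bin; bins with fewer than 3 stations or zero variance are flagged
    not computable.  A ``pooled`` row uses every station and an ``unbinned``
    row reports the stations outside all bins.

    Returns
    -------
    StratifiedPearsonResult
    """
    if bins is None:
        bins = IronBins()
    validate_station_table(table)
    if y is None:
        shares = isip_share(table, gene)
        work = table.loc[shares.index].copy()
        ycol = f"{gene}_share_norm"
        work[ycol] = shares[ycol]
    else:
        work = table.copy()
        ycol = y
        if ycol not in work.columns:
            raise InvalidInputError(f"column {ycol!r} not in table")
    assignment = bins.assign(work["iron"])

    rows = []

    def add_row(label: str, sub: pd.DataFrame) -> None:
        r, p, ok = _pearson(sub[x].to_numpy(float), sub[ycol].to_numpy(float))
        rows.append({"bin": label, "n": len(sub), "r": r, "p": p, "computable": ok})

    for k in range(len(bins.intervals)):
        add_row(bins.label(k), work[assignment == k])
    add_row("pooled", work)
    add_row("unbinned", work[assignment == -1])

    return StratifiedPearsonResult(table=pd.DataFrame(rows), x=x, y=ycol, bins=bins)


def relative_expression_ddct(
    ct_target: float, ct_reference: float, ct_target_cal: float, ct_reference_cal: float
) -> float:
    """Relative expression by the 2^−ΔΔCt method.

    ΔΔCt = (Ct_target − Ct_reference) − (Ct_target,calibrator −
    Ct_reference,calibrator); the fold change is 2^−ΔΔCt.  One cycle less
    than the calibrator (references equal) doubles the expression.
    """
    values = (ct_target, ct_reference, ct_target_cal, ct_reference_cal)
    if not all(np.isfinite(values)):
        raise InvalidInputError("all Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return float(2.0 ** (-ddct))


def tara_adapter_stub() -> None:
    """Documented route to the real metatranscriptome counterpart (no-op).

    The synthetic station tables emulate diatom unigene expression derived
    from ENA accession PRJEB6609 combined with PANGAEA environmental tables
    (dissolved iron, chlorophyll).  An adapter would map those sources onto
    the :data:`REQUIRED_COLUMNS` schema; it is intentionally not implemented
    here because the analysis pipeline is exercised on synthetic tables.
    """
    raise NotImplementedError(
        "Real-data adapter not implemented; construct a DataFrame with "
        f"columns {REQUIRED_COLUMNS} from ENA PRJEB6609 + PANGAEA exports."
    )
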