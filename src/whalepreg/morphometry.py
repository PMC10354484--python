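"""Drone-photogrammetry body widths: standardization, filtering, aggregation.

Body widths measured at 5% increments between 20% and 70% of total length
are standardized by total length (TL), giving unitless, scale-invariant
ratios.  Only the width at 50% of TL (W50, near the widest point of a
gray whale's profile) enters the pregnancy models.  Measurements from the
early feeding season are excluded — whales recently arrived from the
fasting migration are thin regardless of state — keeping only dates
strictly after 26 August.  Within a whale-year the maximum W50 is used,
as pregnant females grow wider over the season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date

import pandas as pd

logger = logging.getLogger(__name__)

#: late-season cut-off (month, day): keep strictly after this date
LATE_SEASON_CUTOFF = (8, 26)

WIDTH_POSITIONS = tuple(range(20, 75, 5))

__all__ = [
    "MorphMeasurement",
    "AnnualW50",
    "standardize_width",
    "late_season_filter",
    "aggregate_annual_w50",
    "process_morph",
]


@dataclass(frozen=True)
class MorphMeasurement:
    whale_id: str
    date: str  # ISO-8601
    tl_mean: float
    tl_sd: float
    widths: dict  # position (% of TL) -> (mean, sd), standardized

    def __post_init__(self):
        for p, (m, s) in self.widths.items():
            if p not in WIDTH_POSITIONS:
                raise ValueError(f"width position {p} not in 20..70 by 5")
            if not (0.0 < m < 1.0):
                raise ValueError(f"standardized width {m} at {p}% outside (0, 1)")
            if s is not None and s < 0:
                raise ValueError("width sd must be non-negative")

    @property
    def w50(self):
        return self.widths.get(50)


@dataclass(frozen=True)
class AnnualW50:
    whale_id: str
    year: int
    w50_mean: float
    w50_sd: float | None
    n_measurements: int
    date: str = ""


def standardize_width(width_m: float, tl_m: float) -> float:
    """Width in metres -> width/TL ratio (unitless)."""
    if not (width_m > 0 and tl_m > 0):
        raise ValueError("width and TL must be positive")
    if width_m >= tl_m:
        raise ValueError(f"width {width_m} m >= TL {tl_m} m: implausible measurement")
    return width_m / tl_m


def late_season_filter(date) -> bool:
    """True = keep: the date falls strictly after 26 August of its year."""
    if isinstance(date, str):
        date = _date.fromisoformat(date)
    return (date.month, date.day) > LATE_SEASON_CUTOFF


def aggregate_annual_w50(measurements: list[MorphMeasurement]) -> AnnualW50 | None:
    """Maximum-W50 rule for one whale-year.

    Picks the measurement with the largest W50 posterior mean and carries
    its posterior sd; ties break toward the most recent date (closest to
    putative late gestation).  Empty input -> None.
    """
    ms = [m for m in measurements if m.w50 is not None]
    if not ms:
        return None
    whales = {m.whale_id for m in ms}
    years = {str(m.date)[:4] for m in ms}
    if len(whales) > 1 or len(years) > 1:
        raise ValueError("measurements span multiple whale-years")
    best = max(ms, key=lambda m: (m.w50[0], str(m.date)))
    return AnnualW50(
        whale_id=best.whale_id,
        year=int(str(best.date)[:4]),
        w50_mean=best.w50[0],
        w50_sd=best.w50[1],
        n_measurements=len(ms),
        date=str(best.date),
    )


def process_morph(morph: pd.DataFrame, apply_late_filter: bool = True) -> pd.DataFrame:
    """Measurement rows -> one annual W50 (with TL) per whale-year.

    ``morph`` columns: whale_id, date, tl_mean, tl_sd, w{p}_mean and
    optionally w{p}_sd for p in 20..70 by 5 (standardized ratios).
    Returns (whale_id, year, w50_mean, w50_sd, tl_mean, tl_sd,
    n_measurements); whale-years with no measurement after the
    late-season filter are absent from the output.
    """
    required = {"whale_id", "date", "tl_mean", "tl_sd", "w50_mean"}
    missing = required - set(morph.columns)
    if missing:
        raise ValueError(f"morph table missing columns {sorted(missing)}")

    kept: dict[tuple[str, int], list[MorphMeasurement]] = {}
    n_early = 0
    for _, row in morph.iterrows():
        if apply_late_filter and not late_season_filter(str(row["date"])):
            n_early += 1
            continue
        widths = {}
        for p in WIDTH_POSITIONS:
            mcol = f"w{p}_mean"
            if mcol in morph.columns and not pd.isna(row[mcol]):
                scol = f"w{p}_sd"
                sd = None
                if scol in morph.columns and not pd.isna(row.get(scol)):
                    sd = float(row[scol])
                widths[p] = (float(row[mcol]), sd)
        if 50 not in widths:
            continue
        m = MorphMeasurement(
            whale_id=str(row["whale_id"]),
            date=str(row["date"]),
            tl_mean=float(row["tl_mean"]),
            tl_sd=float(row["tl_sd"]),
            widths=widths,
        )
        kept.setdefault((m.whale_id, int(str(m.date)[:4])), []).append(m)
    logger.info(
        "late-season filter: %d measurements excluded (on or before %02d-%02d)",
        n_early,
        *LATE_SEASON_CUTOFF,
    )

    rows = []
    for (whale_id, year), ms in sorted(kept.items()):
        annual = aggregate_annual_w50(ms)
        if annual is None:
            continue
        sel = next(m for m in ms if str(m.date) == annual.date)
        rows.append(
            {
                "whale_id": whale_id,
                "year": year,
                "w50_mean": annual.w50_mean,
                "w50_sd": annual.w50_sd,
                "tl_mean": sel.tl_mean,
                "tl_sd": sel.tl_sd,
                "n_measurements": annual.n_measurements,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["whale_id", "year", "w50_mean", "w50_sd", "tl_mean", "tl_sd", "n_measurements"],
    )
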