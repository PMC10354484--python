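"""Whale-year records: maturity, reproductive class, and dataset assembly.

Reproductive classes follow the field convention for female gray whales:

* PF — presumed pregnant: seen with a calf the year after sampling;
* LF — lactating: seen with a calf in the sampling year;
* JF — juvenile: immature female;
* MF — mature female of unknown pregnancy status.

A female is mature when her known or minimum age (the length of her
photo-identification sighting history, LSH) is at least 8 years — the
mean age at sexual maturity for gray whales — or, failing that, when
more than half of her total-length posterior lies above 11.7 m, the
average female length at maturity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

MATURITY_AGE_YEARS = 8
MATURITY_LENGTH_M = 11.7

__all__ = [
    "SightingHistory",
    "AgeEstimate",
    "LengthPosterior",
    "WhaleYearRecord",
    "MaturityIndeterminateError",
    "classify_maturity",
    "assign_repro_class",
    "build_dataset",
    "read_sightings",
]


class MaturityIndeterminateError(ValueError):
    """Maturity cannot be decided: no usable age and no length posterior."""


@dataclass(frozen=True)
class SightingHistory:
    whale_id: str
    first_year: int
    first_seen_as_calf: bool
    calf_years: frozenset = frozenset()
    sex_source: str = "observation"

    def __post_init__(self):
        object.__setattr__(self, "calf_years", frozenset(int(y) for y in self.calf_years))
        if any(y < self.first_year for y in self.calf_years):
            raise ValueError(
                f"{self.whale_id}: calf year precedes first sighting year {self.first_year}"
            )

    def age_estimate(self, year: int) -> "AgeEstimate":
        """Age in ``year`` from the sighting history: whole years since the
        first sighting; 'known' only if first seen as a calf."""
        lsh = int(year) - self.first_year
        if lsh < 0:
            raise ValueError(f"{self.whale_id}: sampled in {year} before first sighting")
        return AgeEstimate(lsh=lsh, age_type="known" if self.first_seen_as_calf else "minimum")


@dataclass(frozen=True)
class AgeEstimate:
    lsh: int
    age_type: str  # "known", "minimum" or "unknown"

    def __post_init__(self):
        if self.age_type not in ("known", "minimum", "unknown"):
            raise ValueError(f"bad age_type {self.age_type!r}")
        if self.lsh < 0:
            raise ValueError("LSH must be non-negative")


@dataclass(frozen=True)
class LengthPosterior:
    tl_mean: float
    tl_sd: float

    def __post_init__(self):
        if not self.tl_mean > 0:
            raise ValueError("tl_mean must be positive")
        if self.tl_sd < 0:
            raise ValueError("tl_sd must be non-negative")

    def prob_longer_than(self, threshold_m: float) -> float:
        """P(TL > threshold) under a normal approximation to the posterior."""
        if self.tl_sd == 0:
            return float(self.tl_mean > threshold_m)
        return float(norm.sf(threshold_m, loc=self.tl_mean, scale=self.tl_sd))


@dataclass
class WhaleYearRecord:
    whale_id: str
    year: int
    repro_class: str
    age: AgeEstimate | None = None
    length: LengthPosterior | None = None
    log_fp4m: float | None = None
    w50: float | None = None
    w50_sd: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.repro_class not in ("PF", "LF", "JF", "MF"):
            raise ValueError(f"bad reproductive class {self.repro_class!r}")
        if self.log_fp4m is None and self.w50 is None:
            raise ValueError(f"{self.whale_id} {self.year}: no measurement present")
        if self.w50 is not None and not (0.0 < self.w50 < 1.0):
            raise ValueError(f"{self.whale_id} {self.year}: W50 must be in (0, 1)")

    @property
    def record_id(self) -> str:
        return f"{self.whale_id}:{self.year}"


def classify_maturity(age: AgeEstimate, length: LengthPosterior | None = None) -> str:
    """'mature' or 'juvenile' from age (LSH) and, if needed, body length.

    A known or minimum age of at least 8 years means mature.  A female
    first seen as a calf less than 8 years ago is a juvenile.  Otherwise
    (unknown age, or a minimum age below 8 that cannot exclude maturity)
    the call falls to the length posterior: mature iff P(TL > 11.7 m) >
    0.5; exactly 0.5 is resolved to juvenile (conservative).
    """
    if age.age_type in ("known", "minimum") and age.lsh >= MATURITY_AGE_YEARS:
        return "mature"
    if age.age_type == "known":
        return "juvenile"
    # unknown age, or minimum age below the maturity threshold
    if length is None:
        raise MaturityIndeterminateError(
            f"maturity indeterminate: age_type={age.age_type!r}, lsh={age.lsh} "
            "and no length posterior supplied"
        )
    return "mature" if length.prob_longer_than(MATURITY_LENGTH_M) > 0.5 else "juvenile"


def assign_repro_class(maturity: str, sampling_year: int, calf_years) -> str:
    """PF / LF / JF / MF from maturity and the calf-sighting record.

    A calf the year after sampling means the female was pregnant when
    sampled (PF); a calf in the sampling year means lactating (LF).
    Lactating gray whales are not known to produce a new calf the next
    year, so both at once is a validation error.
    """
    if maturity not in ("mature", "juvenile"):
        raise ValueError(f"bad maturity {maturity!r}")
    calf_years = {int(y) for y in calf_years}
    next_year = sampling_year + 1 in calf_years
    this_year = sampling_year in calf_years
    if next_year and this_year:
        raise ValueError(
            f"calf seen in both {sampling_year} and {sampling_year + 1}: "
            "biologically excluded (lactation lasts ~7 months and annual "
            "calving does not follow lactation)"
        )
    if next_year:
        return "PF"
    if this_year:
        return "LF"
    return "JF" if maturity == "juvenile" else "MF"


def read_sightings(path) -> dict[str, SightingHistory]:
    """Parse sightings.csv (whale_id, first_year, first_seen_as_calf,
    calf_years semicolon-separated, sex_source) with line-numbered errors."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"whale_id", "first_year", "first_seen_as_calf", "calf_years"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, SightingHistory] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            calf_years = frozenset(
                int(tok) for tok in str(row["calf_years"]).split(";") if tok.strip()
            )
            hist = SightingHistory(
                whale_id=row["whale_id"],
                first_year=int(row["first_year"]),
                first_seen_as_calf=str(row["first_seen_as_calf"]).strip().lower()
                in ("true", "yes", "1"),
                calf_years=calf_years,
                sex_source=row.get("sex_source", "observation") or "observation",
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path} line {line}: {err}") from err
        if hist.whale_id in out:
            raise ValueError(f"{path} line {line}: duplicate whale_id {hist.whale_id!r}")
        out[hist.whale_id] = hist
    return out


def build_dataset(
    sightings: dict[str, SightingHistory],
    hormone_aggregates: pd.DataFrame,
    morph_aggregates: pd.DataFrame,
) -> list[WhaleYearRecord]:
    """Join annual hormone and width aggregates into whale-year records.

    ``hormone_aggregates`` needs columns (whale_id, year, log_fp4m);
    ``morph_aggregates`` (whale_id, year, w50_mean, w50_sd, tl_mean,
    tl_sd).  One record per whale-year keyed on (whale_id, year);
    whale-years lacking both measurements are dropped with a logged
    count; conflicting duplicate keys raise with the offenders listed.
    """
    for name, df in (("hormone", hormone_aggregates), ("morph", morph_aggregates)):
        if len(df) == 0:
            continue
        dup = df.duplicated(["whale_id", "year"])
        if dup.any():
            offenders = df.loc[dup, ["whale_id", "year"]].to_records(index=False).tolist()
            raise ValueError(f"duplicate (whale_id, year) keys in {name} aggregates: {offenders}")

    keys: list[tuple[str, int]] = []
    for df in (hormone_aggregates, morph_aggregates):
        for _, row in df.iterrows():
            k = (str(row["whale_id"]), int(row["year"]))
            if k not in keys:
                keys.append(k)

    horm = {
        (str(r["whale_id"]), int(r["year"])): r for _, r in hormone_aggregates.iterrows()
    }
    morph = {(str(r["whale_id"]), int(r["year"])): r for _, r in morph_aggregates.iterrows()}

    records: list[WhaleYearRecord] = []
    n_dropped = 0
    for whale_id, year in keys:
        h = horm.get((whale_id, year))
        m = morph.get((whale_id, year))
        log_fp4m = None if h is None or pd.isna(h["log_fp4m"]) else float(h["log_fp4m"])
        w50 = None if m is None or pd.isna(m["w50_mean"]) else float(m["w50_mean"])
        if log_fp4m is None and w50 is None:
            n_dropped += 1
            continue
        w50_sd = None
        length = None
        if m is not None:
            if "w50_sd" in m and not pd.isna(m["w50_sd"]):
                w50_sd = float(m["w50_sd"])
            if "tl_mean" in m and not pd.isna(m["tl_mean"]):
                length = LengthPosterior(float(m["tl_mean"]), float(m.get("tl_sd", 0.0) or 0.0))
        if whale_id not in sightings:
            raise KeyError(f"no sighting history for {whale_id!r}")
        hist = sightings[whale_id]
        age = hist.age_estimate(year)
        maturity = classify_maturity(age, length)
        repro = assign_repro_class(maturity, year, hist.calf_years)
        records.append(
            WhaleYearRecord(
                whale_id=whale_id,
                year=year,
                repro_class=repro,
                age=age,
                length=length,
                log_fp4m=log_fp4m,
                w50=w50,
                w50_sd=w50_sd,
                provenance={
                    "n_fp4m_samples": None if h is None else int(h.get("n_samples", 0) or 0),
                    "n_morph": None if m is None else int(m.get("n_measurements", 0) or 0),
                },
            )
        )
    if n_dropped:
        logger.info("dropped %d whale-years lacking both measurements", n_dropped)
    return records


def records_to_frame(records: list[WhaleYearRecord]) -> pd.DataFrame:
    """Flatten whale-year records into the analysis table."""
    return pd.DataFrame(
        {
            "whale_id": [r.whale_id for r in records],
            "year": [r.year for r in records],
            "group": [r.repro_class for r in records],
            "lsh": [None if r.age is None else r.age.lsh for r in records],
            "age_type": [None if r.age is None else r.age.age_type for r in records],
            "tl_mean": [None if r.length is None else r.length.tl_mean for r in records],
            "tl_sd": [None if r.length is None else r.length.tl_sd for r in records],
            "fp4m_log": [r.log_fp4m for r in records],
            "w50": [r.w50 for r in records],
            "w50_sd": [r.w50_sd for r in records],
            "record_id": [r.record_id for r in records],
        }
    )
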