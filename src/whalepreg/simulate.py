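"""Synthetic gray-whale datasets with the structure the analysis assumes.

The generator emits the same three CSV payloads the real pipeline
ingests — faecal assay rows, photogrammetry measurement rows and
sighting histories — plus a ground-truth pregnancy state per whale-year,
so every preprocessing stage and the full model pipeline can be
exercised and parameter recovery asserted without any field data.

Class-conditional defaults emulate the study population summaries:
overlapping log-fP4m components (pregnant N(4.60, 1.15^2), non-pregnant
N(4.10, 0.77^2) on the log ng g^-1 scale — the overlap is deliberate, it
is the documented failure mode of the hormone variable) and
well-separated W50 components (pregnant N(0.178, 0.01^2), non-pregnant
N(0.15, 0.01^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hormones import DEFAULT_LOD_PGML

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "truth_table"]

# relative body-width profile along the axis, peaking near mid-body
_WIDTH_PROFILE = {20: 0.72, 25: 0.82, 30: 0.90, 35: 0.95, 40: 0.98, 45: 1.0,
                  50: 1.0, 55: 0.97, 60: 0.90, 65: 0.78, 70: 0.62}


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Counts default to the study's observed whale-years per class; the
    mixture components to the published group summaries.  ``w50_measurement_sd``
    is the photogrammetric posterior sd attached to each width
    measurement; ``mf_pregnant_fraction`` sets how many mature females of
    unknown status are truly pregnant (their calves are never observed —
    the calf-loss / unobserved-calf ambiguity); ``calf_loss_rate``
    additionally converts that fraction of would-be PF whale-years into
    MF by removing the next-year calf sighting.
    """

    n_per_class: dict = field(
        default_factory=lambda: {"PF": 5, "LF": 4, "JF": 19, "MF": 48}
    )
    fp4m_log_pregnant: tuple = (4.60, 1.15)  # (mean, sd) of log ng g^-1
    fp4m_log_nonpregnant: tuple = (4.10, 0.77)
    w50_pregnant: tuple = (0.178, 0.01)
    w50_nonpregnant: tuple = (0.15, 0.01)
    w50_measurement_sd: float = 0.005
    mf_pregnant_fraction: float = 0.15
    calf_loss_rate: float = 0.0
    lod_pgml: float = DEFAULT_LOD_PGML
    p_below_lod: float = 0.05
    p_small_mass: float = 0.05
    p_duplicate_day: float = 0.08
    p_early_season: float = 0.15
    samples_per_whale_year: tuple = (1, 3)
    measurements_per_whale_year: tuple = (1, 3)
    fp4m_sample_sd: float = 0.30  # within-year log-scale sampling noise
    assay_cv: float = 0.08  # duplicate-well relative noise
    first_season: int = 2016
    n_seasons: int = 6

    def validate(self):
        for name in ("mf_pregnant_fraction", "calf_loss_rate", "p_below_lod",
                     "p_small_mass", "p_duplicate_day", "p_early_season"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("fp4m_log_pregnant", "fp4m_log_nonpregnant",
                     "w50_pregnant", "w50_nonpregnant"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be non-negative")
        if self.w50_measurement_sd < 0:
            raise ValueError("w50_measurement_sd must be non-negative")
        return self


@dataclass
class SimulatedDataset:
    assays: pd.DataFrame
    morph: pd.DataFrame
    sightings: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir):
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.assays.to_csv(out / "assays.csv", index=False)
        self.morph.to_csv(out / "morph.csv", index=False)
        self.sightings.to_csv(out / "sightings.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        return out


def _iso(year: int, month: int, day: int) -> str:
    return f"{year:04d}-{month:02d}-{day:02d}"


def _draw_date(rng, year: int, early: bool) -> str:
    """A field date: early season (June to 26 Aug) or late (27 Aug to mid Oct)."""
    if early:
        day_of = int(rng.integers(0, 86))  # 1 Jun .. 25 Aug
        month, day = (6, 1 + day_of) if day_of < 30 else (
            (7, day_of - 29) if day_of < 61 else (8, day_of - 60)
        )
    else:
        day_of = int(rng.integers(0, 50))  # 27 Aug .. 15 Oct
        if day_of < 4:
            month, day = 8, 27 + day_of
        elif day_of < 34:
            month, day = 9, day_of - 3
        else:
            month, day = 10, day_of - 33
    return _iso(year, month, day)


def simulate_dataset(config: SimulationConfig | None = None, rng=None) -> SimulatedDataset:
    """Generate one synthetic dataset under ``config``.

    Deterministic given the same config and seeded generator.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(rng)

    whale_rows = []
    sighting_rows = []
    assay_rows = []
    morph_rows = []
    serial = 0

    for cls, count in config.n_per_class.items():
        if cls not in ("PF", "LF", "JF", "MF"):
            raise ValueError(f"unknown class {cls!r}")
        for _ in range(int(count)):
            serial += 1
            whale_id = f"Sim-{serial:04d}"
            year = config.first_season + int(rng.integers(0, config.n_seasons))

            observed_cls = cls
            if cls == "PF":
                pregnant = True
                if rng.uniform() < config.calf_loss_rate:
                    observed_cls = "MF"  # calf lost before resighting
            elif cls == "MF":
                pregnant = bool(rng.uniform() < config.mf_pregnant_fraction)
            else:
                pregnant = False

            if observed_cls == "JF":
                lsh = int(rng.integers(1, 8))
                first_as_calf = True
                tl = rng.normal(9.0 + 0.35 * lsh, 0.4)
            else:
                lsh = int(rng.integers(8, 26))
                first_as_calf = False
                tl = rng.normal(12.3, 0.5)
            tl = float(np.clip(tl, 8.0, 15.5))

            calf_years = []
            if observed_cls == "PF":
                calf_years.append(year + 1)
            if observed_cls == "LF":
                calf_years.append(year)
            sighting_rows.append(
                {
                    "whale_id": whale_id,
                    "first_year": year - lsh,
                    "first_seen_as_calf": first_as_calf,
                    "calf_years": ";".join(str(y) for y in calf_years),
                    "sex_source": "observation" if calf_years else "faecal-genetics",
                }
            )

            # annual latent levels for the two diagnostics
            mu_f, sd_f = (
                config.fp4m_log_pregnant if pregnant else config.fp4m_log_nonpregnant
            )
            mu_w, sd_w = config.w50_pregnant if pregnant else config.w50_nonpregnant
            log_fp4m_year = rng.normal(mu_f, sd_f)
            w50_year = float(np.clip(rng.normal(mu_w, sd_w), 0.08, 0.30))

            # --- faecal samples ------------------------------------------
            lo, hi = config.samples_per_whale_year
            n_samp = int(rng.integers(lo, hi + 1))
            for s in range(n_samp):
                date = _draw_date(rng, year, early=bool(rng.uniform() < 0.5))
                n_jars = 2 if rng.uniform() < config.p_duplicate_day else 1
                for jar in range(n_jars):
                    ngg = float(np.exp(rng.normal(log_fp4m_year, config.fp4m_sample_sd)))
                    if rng.uniform() < config.p_small_mass:
                        mass = float(rng.uniform(0.002, 0.019))
                    else:
                        mass = float(rng.uniform(0.05, 1.5))
                    volume = mass * float(rng.uniform(10, 25))
                    dilution = 1.0
                    pgml = ngg * 1000.0 * mass / (dilution * volume)
                    if rng.uniform() < config.p_below_lod:
                        pgml = float(rng.uniform(0.2, 0.95) * config.lod_pgml)
                    eps = rng.normal(0.0, config.assay_cv, size=2)
                    assay_rows.append(
                        {
                            "sample_id": f"{whale_id}-{year}-{s}{chr(97 + jar)}",
                            "whale_id": whale_id,
                            "date": date,
                            "rep1_pgml": max(pgml * (1 + eps[0]), 0.05),
                            "rep2_pgml": max(pgml * (1 + eps[1]), 0.05),
                            "dilution": dilution,
                            "extract_volume_ml": volume,
                            "dry_mass_g": mass,
                            "pooled": False,
                        }
                    )

            # --- photogrammetry measurements -----------------------------
            lo, hi = config.measurements_per_whale_year
            n_meas = int(rng.integers(lo, hi + 1))
            early_flags = [bool(rng.uniform() < config.p_early_season) for _ in range(n_meas)]
            early_flags[int(rng.integers(0, n_meas))] = False  # keep >=1 late-season
            for early in early_flags:
                w50_meas = w50_year + rng.normal(0.0, config.w50_measurement_sd)
                row = {
                    "whale_id": whale_id,
                    "date": _draw_date(rng, year, early=early),
                    "tl_mean": round(tl + rng.normal(0, 0.05), 2),
                    "tl_sd": round(float(rng.uniform(0.1, 0.5)), 2),
                }
                for p, rel in _WIDTH_PROFILE.items():
                    if p == 45:
                        continue
                    w = w50_meas * rel + rng.normal(0.0, config.w50_measurement_sd / 2)
                    row[f"w{p}_mean"] = float(np.clip(w, 0.05, 0.35))
                    row[f"w{p}_sd"] = config.w50_measurement_sd
                morph_rows.append(row)

            whale_rows.append(
                {
                    "whale_id": whale_id,
                    "year": year,
                    "class": observed_cls,
                    "designated_class": cls,
                    "pregnant": pregnant,
                    "log_fp4m_latent": log_fp4m_year,
                    "w50_latent": w50_year,
                }
            )

    return SimulatedDataset(
        assays=pd.DataFrame(assay_rows),
        morph=pd.DataFrame(morph_rows),
        sightings=pd.DataFrame(sighting_rows),
        truth=pd.DataFrame(whale_rows),
        config=config,
    )


def truth_table(dataset: SimulatedDataset) -> pd.DataFrame:
    """Ground-truth labels per whale-year for oracle evaluation."""
    t = dataset.truth.copy()
    t["record_id"] = t["whale_id"] + ":" + t["year"].astype(str)
    return t[["record_id", "whale_id", "year", "class", "pregnant"]]
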