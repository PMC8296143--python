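"""Raw field-plot records.

One :class:`PlotRecord` is one plot in one trial year of the non-replicated
augmented design: layout coordinates, the genotype sown, and every raw
measurement the trait-derivation step consumes (growth-stage dates as
day-of-cycle offsets from sowing, ceptometer PAR triplets, biomass cuts,
canopy/air temperature pairs, green-area image series, harvest sample
counts/weights and the machine-harvested plot yield).

Records round-trip through a flat CSV (one row per plot-year); the dated
PAR and green-area series are stored as compact JSON strings in their
columns.  The column schema is documented in ``docs/plot_records_schema.md``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class ParSample:
    """One ceptometer reading: incident, transmitted, reflected PAR.

    ``day`` may be fractional (readings are instantaneous); the three fluxes
    share units (only their ratios matter).
    """

    day: float
    par_i: float
    par_t: float
    par_r: float


@dataclass
class GaSample:
    """Green-area estimate from one plot image."""

    day: float
    ga: float


@dataclass
class PlotRecord:
    year: int
    plot: int
    row: int
    col: int
    genotype: str
    is_check: bool

    # growth stages, day offsets from sowing (None = not recorded)
    gs11: int | None = None   # emergence
    gs55: int | None = None   # heading
    gs65: int | None = None   # anthesis
    gs87: int | None = None   # physiological maturity

    # radiation
    par_samples: list[ParSample] = field(default_factory=list)
    incident_par_daily: float = 12.0          # MJ m-2 day-1 incident PAR

    # biomass cut at anthesis (0.5 m of a central row)
    dm_a_sample_g: float | None = None
    dm_sample_row_length_m: float = 0.5

    # canopy temperature (three readings per occasion)
    ta_anthesis: float | None = None
    tc_anthesis: tuple[float, ...] = ()
    ta_milky: float | None = None
    tc_milky: tuple[float, ...] = ()

    # green-area image series
    ga_samples: list[GaSample] = field(default_factory=list)

    # pre-harvest 1 m row sample
    harvest_row_length_m: float = 1.0
    row_spacing_m: float = 0.15
    spikes: float | None = None
    grains: float | None = None
    grain_mass_g: float | None = None
    total_mass_g: float | None = None

    # grain-weight subsample drawn from the harvested grain
    subsample_mass_g: float = 10.0
    subsample_grain_count: float | None = None

    # stem measurements (three main stems)
    ph_cm: tuple[float, ...] = ()
    pl_cm: tuple[float, ...] = ()

    # machine harvest
    plot_yield_kg: float | None = None
    plot_area_m2: float = 3.6
    moisture_factor: float = 1.0


_SERIES_COLS = ("par_samples", "ga_samples")
_TUPLE_COLS = ("tc_anthesis", "tc_milky", "ph_cm", "pl_cm")


def records_to_frame(records: list[PlotRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["par_samples"] = json.dumps(
            [[s["day"], s["par_i"], s["par_t"], s["par_r"]] for s in d["par_samples"]]
        )
        d["ga_samples"] = json.dumps([[s["day"], s["ga"]] for s in d["ga_samples"]])
        for c in _TUPLE_COLS:
            d[c] = json.dumps(list(d[c]))
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[PlotRecord]:
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        d["par_samples"] = [ParSample(*v) for v in json.loads(d["par_samples"])]
        d["ga_samples"] = [GaSample(*v) for v in json.loads(d["ga_samples"])]
        for c in _TUPLE_COLS:
            d[c] = tuple(json.loads(d[c]))
        for c in ("gs11", "gs55", "gs65", "gs87"):
            d[c] = None if pd.isna(d[c]) else int(d[c])
        for c in (
            "dm_a_sample_g", "ta_anthesis", "ta_milky", "spikes", "grains",
            "grain_mass_g", "total_mass_g", "subsample_grain_count",
            "plot_yield_kg",
        ):
            if pd.isna(d[c]):
                d[c] = None
        d["is_check"] = bool(d["is_check"])
        d["year"] = int(d["year"])
        d["plot"] = int(d["plot"])
        d["row"] = int(d["row"])
        d["col"] = int(d["col"])
        out.append(PlotRecord(**d))
    return out


def write_records_csv(records: list[PlotRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[PlotRecord]:
    return frame_to_records(pd.read_csv(path))
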