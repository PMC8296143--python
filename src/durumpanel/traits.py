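"""Derivation of the 21 agro-physiological traits from raw plot records.

Phenology is kept in calendar days (day-of-cycle offsets from sowing).
Radiation bookkeeping works on the fraction of photosynthetically active
radiation intercepted by the canopy (IPAR, measured as ceptometer triplets
of incident/transmitted/reflected flux); the cumulated absorbed PAR of a
growth period (cPAR, MJ m-2) integrates the daily-interpolated IPAR fraction
against daily incident PAR.  Radiation-use efficiency (RUE, g MJ-1) is the
biomass gained per unit absorbed PAR between two sampling dates.

Missing-data policy: a missing raw input yields a missing (NaN) trait value,
never an imputed zero; physically inconsistent inputs (out-of-order stages,
interception above incident flux) raise ``ValueError``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GaSample, ParSample, PlotRecord

log = logging.getLogger(__name__)

#: Traits the field pipeline reports, in canonical order.
ALL_TRAITS = [
    "Yield", "NS", "NGS", "W", "HI",
    "D_EH", "D_HA", "D_AM", "GFR", "PL", "PH",
    "DM_A", "DM_M", "CTD_A", "CTD_Mi",
    "cPAR_EH", "cPAR_HA", "cPAR_AM", "RUE_EA", "RUE_AM", "GA_90d",
]

#: Traits that are ratios/differences of the others and cannot be set
#: independently of them: GFR = W / D_AM, DM_M follows from the harvest
#: sample (NS*NGS*W and HI), RUE_EA = DM_A / (cPAR_EH + cPAR_HA),
#: RUE_AM = (DM_M - DM_A) / cPAR_AM.
DERIVED_TRAITS = ["GFR", "DM_M", "RUE_EA", "RUE_AM"]

#: Independently measurable traits a simulated QTL may act on.
PRIMARY_TRAITS = [t for t in ALL_TRAITS if t not in DERIVED_TRAITS]


@dataclass
class GrowthStages:
    """Zadoks growth-stage dates as integer day offsets from sowing."""

    gs11: int | None  # first leaf emerged
    gs55: int | None  # heading
    gs65: int | None  # anthesis
    gs87: int | None  # physiological maturity


@dataclass
class CanopyTempSample:
    ta: float                   # air temperature, degC
    tc: tuple[float, ...]       # three canopy readings, degC


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------

def derive_phenology(gs: GrowthStages) -> tuple[float, float, float]:
    """Durations (D_EH, D_HA, D_AM) in whole days; missing dates propagate.

    Raises ``ValueError`` if the recorded dates are out of order.
    """
    present = [d for d in (gs.gs11, gs.gs55, gs.gs65, gs.gs87) if d is not None]
    if any(b < a for a, b in zip(present, present[1:])):
        raise ValueError(f"growth stages out of order: {gs}")

    def diff(a, b):
        return float(b - a) if a is not None and b is not None else np.nan

    return diff(gs.gs11, gs.gs55), diff(gs.gs55, gs.gs65), diff(gs.gs65, gs.gs87)


def ipar_percent(s: ParSample) -> float:
    """Percent of incident PAR intercepted: 100*(PARi - PARt - PARr)/PARi."""
    if s.par_i <= 0:
        raise ValueError("incident PAR must be positive")
    if s.par_t < 0 or s.par_r < 0 or s.par_t + s.par_r > s.par_i * (1 + 1e-9):
        raise ValueError("transmitted + reflected PAR exceeds incident")
    return 100.0 * (s.par_i - s.par_t - s.par_r) / s.par_i


def cumulate_par(
    ipar_samples,
    incident_daily,
    d_start: int,
    d_end: int,
) -> float:
    """Absorbed PAR (MJ m-2) over the integer-day interval [d_start, d_end).

    ``ipar_samples`` is a sequence of ``(day, ipar_percent)`` pairs; the daily
    IPAR fraction is linearly interpolated between sample days and held
    constant before the first / after the last sample.  ``incident_daily`` is
    the incident PAR in MJ m-2 day-1: a scalar, or a mapping day -> value.

    The half-open convention makes the quantity additive over adjacent
    periods: cPAR[a,b) + cPAR[b,c) == cPAR[a,c).
    """
    if d_end <= d_start:
        return 0.0
    samples = sorted(ipar_samples)
    if not samples:
        raise ValueError("no IPAR samples")
    days = np.arange(d_start, d_end)
    xs = np.array([s[0] for s in samples], dtype=float)
    ys = np.array([s[1] for s in samples], dtype=float) / 100.0
    frac = np.interp(days, xs, ys)
    if np.isscalar(incident_daily):
        inc = np.full(days.shape, float(incident_daily))
    else:
        inc = np.array([float(incident_daily[int(d)]) for d in days])
    return float(np.sum(frac * inc))


def rue(dm_end: float, dm_start: float, cpar_end: float, cpar_start: float) -> float:
    """Radiation-use efficiency (DMn - DMn-1)/(cPARn - cPARn-1), g MJ-1."""
    if cpar_end < cpar_start:
        raise ValueError("cPAR must be non-decreasing between sampling dates")
    if cpar_end == cpar_start:
        log.warning("equal cPAR at both sampling dates; RUE undefined")
        return np.nan
    return (dm_end - dm_start) / (cpar_end - cpar_start)


def ctd(s: CanopyTempSample) -> float:
    """Canopy temperature depression Ta - mean(Tc); positive = cooler canopy."""
    if len(s.tc) < 3:
        return np.nan
    return s.ta - float(np.mean(s.tc))


def grain_filling_rate(w_mg: float, d_am: float) -> float:
    """Mean grain-filling rate W / D_AM in mg day-1; D_AM <= 0 -> missing."""
    if d_am is None or not np.isfinite(d_am) or d_am <= 0:
        return np.nan
    return w_mg / d_am


def ga_90d(ga_samples, emergence_day: int) -> float:
    """Green area accumulated over days 1..90 from emergence.

    Daily values come from linear interpolation between image dates, with
    constant extrapolation outside the sampled range.  A single sample is
    accepted (constant profile) with a warning; samples that all fall after
    day 90 from emergence cannot inform the window and raise ``ValueError``.
    """
    samples = sorted(ga_samples)
    if not samples:
        raise ValueError("no green-area samples")
    xs = np.array([s[0] for s in samples], dtype=float) - emergence_day
    if xs.min() > 90:
        raise ValueError("all green-area samples fall after day 90 from emergence")
    if len(samples) == 1:
        warnings.warn("single green-area sample; constant extrapolation", stacklevel=2)
    ys = np.array([s[1] for s in samples], dtype=float)
    days = np.arange(1, 91)
    return float(np.sum(np.interp(days, xs, ys)))


def yield_components(
    spikes: float,
    grains: float,
    grain_mass_g: float,
    total_mass_g: float,
    row_length_m: float,
    row_spacing_m: float,
    plot_yield_kg: float,
    plot_area_m2: float,
    subsample_mass_g: float,
    subsample_grain_count: float,
    moisture_factor: float = 1.0,
) -> tuple[float, float, float, float, float]:
    """(NS, NGS, W, HI, Yield) from the 1 m row sample and the plot harvest.

    NS is spikes per m-2 of sampled area, NGS grains per spike, W the
    thousand-kernel-derived single-grain weight in mg, HI the grain share of
    total sample mass, and Yield the plot harvest scaled to kg ha-1 with the
    (configured) 12 %-moisture standardization factor applied.
    """
    area = row_length_m * row_spacing_m
    if area <= 0:
        raise ValueError("sampled area must be positive")
    ns = spikes / area
    ngs = grains / spikes if spikes > 0 else np.nan
    w = (
        1000.0 * subsample_mass_g / subsample_grain_count
        if subsample_grain_count and subsample_grain_count > 0
        else np.nan
    )
    hi = grain_mass_g / total_mass_g if total_mass_g > 0 else np.nan
    yld = plot_yield_kg / plot_area_m2 * 10_000.0 * moisture_factor
    return ns, ngs, w, hi, yld


# --------------------------------------------------------------------------
# whole-plot derivation
# --------------------------------------------------------------------------

def _nan_if_none(x):
    return np.nan if x is None else x


def derive_plot_traits(r: PlotRecord) -> dict[str, float]:
    """All 21 trait values for one plot record (NaN where inputs missing)."""
    out: dict[str, float] = {t: np.nan for t in ALL_TRAITS}

    gs = GrowthStages(r.gs11, r.gs55, r.gs65, r.gs87)
    d_eh, d_ha, d_am = derive_phenology(gs)
    out["D_EH"], out["D_HA"], out["D_AM"] = d_eh, d_ha, d_am

    # harvest sample / yield components
    if r.spikes is not None and r.plot_yield_kg is not None:
        ns, ngs, w, hi, yld = yield_components(
            r.spikes, r.grains, r.grain_mass_g, r.total_mass_g,
            r.harvest_row_length_m, r.row_spacing_m,
            r.plot_yield_kg, r.plot_area_m2,
            r.subsample_mass_g, r.subsample_grain_count,
            r.moisture_factor,
        )
        out.update({"NS": ns, "NGS": ngs, "W": w, "HI": hi, "Yield": yld})
        out["GFR"] = grain_filling_rate(w, d_am)
        # aboveground dry matter at maturity from the 1 m row sample
        if r.total_mass_g is not None:
            out["DM_M"] = r.total_mass_g / (r.harvest_row_length_m * r.row_spacing_m)

    if r.dm_a_sample_g is not None:
        out["DM_A"] = r.dm_a_sample_g / (r.dm_sample_row_length_m * r.row_spacing_m)

    if r.ta_anthesis is not None:
        out["CTD_A"] = ctd(CanopyTempSample(r.ta_anthesis, r.tc_anthesis))
    if r.ta_milky is not None:
        out["CTD_Mi"] = ctd(CanopyTempSample(r.ta_milky, r.tc_milky))

    if r.par_samples and None not in (r.gs11, r.gs55, r.gs65, r.gs87):
        ipar = [(s.day, ipar_percent(s)) for s in r.par_samples]
        inc = r.incident_par_daily
        out["cPAR_EH"] = cumulate_par(ipar, inc, r.gs11, r.gs55)
        out["cPAR_HA"] = cumulate_par(ipar, inc, r.gs55, r.gs65)
        out["cPAR_AM"] = cumulate_par(ipar, inc, r.gs65, r.gs87)
        if np.isfinite(out["DM_A"]):
            out["RUE_EA"] = rue(out["DM_A"], 0.0, out["cPAR_EH"] + out["cPAR_HA"], 0.0)
            if np.isfinite(out["DM_M"]):
                out["RUE_AM"] = rue(
                    out["DM_M"], out["DM_A"],
                    out["cPAR_EH"] + out["cPAR_HA"] + out["cPAR_AM"],
                    out["cPAR_EH"] + out["cPAR_HA"],
                )

    if r.ga_samples and r.gs11 is not None:
        out["GA_90d"] = ga_90d([(s.day, s.ga) for s in r.ga_samples], r.gs11)

    if len(r.ph_cm) == 3:
        out["PH"] = float(np.mean(r.ph_cm))
    if len(r.pl_cm) == 3:
        out["PL"] = float(np.mean(r.pl_cm))
    return out


def derive_trait_table(records: list[PlotRecord]) -> pd.DataFrame:
    """Tidy trait table: one row per plot x trait, with layout columns kept."""
    rows = []
    for r in records:
        vals = derive_plot_traits(r)
        for trait in ALL_TRAITS:
            rows.append(
                {
                    "genotype": r.genotype,
                    "year": r.year,
                    "plot": r.plot,
                    "row": r.row,
                    "col": r.col,
                    "is_check": r.is_check,
                    "trait": trait,
                    "value": vals[trait],
                }
            )
    return pd.DataFrame(rows)
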