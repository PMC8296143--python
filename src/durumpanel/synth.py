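"""Synthetic diversity panels and field trials with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a panel of inbred durum genotypes (landraces + modern cultivars)
drawn from admixed genetic subpopulations with Balding–Nichols-style
allele-frequency differentiation, and a multi-year non-replicated augmented
field design (replicated checks at a 1:5 check:test ratio) whose raw plot
measurements are *inverted* from target trait values, so that running the
trait-derivation step on the generated records reproduces the generator's
truth table (exactly when all noise SDs are zero).

Plot-level model for every trait::

    value = baseline + sum(QTL effects) [+ polygenic] + row + col + residual

QTLs act on the independently measurable traits; ratio traits (GFR, DM_M,
RUE_EA, RUE_AM) follow from the others and are recorded as derived.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import CHROMOSOMES, MarkerPanel
from .records import GaSample, ParSample, PlotRecord
from .traits import ALL_TRAITS, DERIVED_TRAITS, PRIMARY_TRAITS

# --------------------------------------------------------------------------
# default trait scales (plot level, trait units)
# --------------------------------------------------------------------------

DEFAULT_BASELINES = {
    "Yield": 4250.0, "NS": 337.0, "NGS": 32.0, "W": 44.3, "HI": 0.42,
    "D_EH": 127.0, "D_HA": 5.4, "D_AM": 32.6, "PL": 40.0, "PH": 92.0,
    "DM_A": 735.0, "CTD_A": 0.9, "CTD_Mi": -0.5,
    "cPAR_EH": 255.0, "cPAR_HA": 36.0, "cPAR_AM": 169.0, "GA_90d": 138.0,
}

DEFAULT_RESIDUAL_SD = {
    "Yield": 250.0, "NS": 20.0, "NGS": 2.0, "W": 2.0, "HI": 0.018,
    "D_EH": 1.8, "D_HA": 0.7, "D_AM": 1.4, "PL": 2.2, "PH": 3.5,
    "DM_A": 45.0, "CTD_A": 0.55, "CTD_Mi": 0.55,
    "cPAR_EH": 10.0, "cPAR_HA": 3.0, "cPAR_AM": 7.0, "GA_90d": 7.0,
}

#: Genetic SD used when the optional polygenic term is switched on
#: (plot-level heritability ~0.5 at the default residual SDs).
DEFAULT_GENETIC_SD = dict(DEFAULT_RESIDUAL_SD)


def _per_trait(value, defaults) -> dict[str, float]:
    """Resolve a scalar scale factor or an absolute per-trait mapping."""
    if value is None:
        return dict(defaults)
    if np.isscalar(value):
        return {t: float(value) * defaults[t] for t in defaults}
    out = dict(defaults)
    out.update({k: float(v) for k, v in value.items()})
    return out


# --------------------------------------------------------------------------
# panel simulation
# --------------------------------------------------------------------------

@dataclass
class SpPrivateRun:
    """A run of consecutive markers fixed for a private allele in one SP.

    Used to plant ground-truth haplotype blocks: within the run the target
    subpopulation is fixed for dosage allele 0 while every other
    subpopulation is fixed for allele 1.
    """

    subpop: int            # 0-based subpopulation index
    chromosome: str
    start_cM: float
    n_markers: int
    span_cM: float = 1.2   # run markers are repositioned evenly over this span


@dataclass
class PanelConfig:
    n_genotypes: int = 372
    n_landraces: int = 172
    n_subpops: int = 5
    n_markers: int = 2000
    frac_pav: float = 0.776          # PAV share of the DArTseq marker mix
    map_length_cM: float = 150.0     # per chromosome
    fst_like_differentiation: float | tuple = 0.10
    admixture_concentration: float = 3.0
    admixture_background: float = 0.35
    ancestral_freq_range: tuple[float, float] = (0.10, 0.90)
    missing_rate: float = 0.03
    high_divergence: dict[int, float] = field(default_factory=dict)  # marker idx -> F
    private_runs: list[SpPrivateRun] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes <= 0 or self.n_markers <= 0 or self.n_subpops <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_landraces <= self.n_genotypes:
            raise ValueError("n_landraces must be within [0, n_genotypes]")
        for name in ("frac_pav", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        fst = np.atleast_1d(self.fst_like_differentiation)
        if (fst < 0).any() or (fst >= 1).any():
            raise ValueError("fst_like_differentiation must be in [0, 1)")
        if self.map_length_cM <= 0:
            raise ValueError("map_length_cM must be positive")


@dataclass
class PanelSim:
    """A simulated panel plus its generative ground truth."""

    panel: MarkerPanel
    q: pd.DataFrame                  # genotypes x SP membership, rows sum to 1
    subpop_freqs: pd.DataFrame       # markers x SP allele-1 frequencies
    ancestral_freq: pd.Series
    home_subpop: pd.Series           # genotype -> 0-based home SP index
    is_landrace: pd.Series


def _bn_freqs(rng, p0: np.ndarray, fst: np.ndarray) -> np.ndarray:
    """Balding–Nichols draw of per-subpop frequencies around p0 (m x k)."""
    m, k = p0.size, fst.size
    out = np.empty((m, k))
    for s in range(k):
        f = fst[s]
        if f <= 0:
            out[:, s] = p0
        else:
            a = p0 * (1.0 - f) / f
            b = (1.0 - p0) * (1.0 - f) / f
            out[:, s] = rng.beta(a, b)
    return out


def simulate_panel(cfg: PanelConfig) -> PanelSim:
    """Simulate markers on the 14-chromosome map and admixed genotypes.

    Same config (incl. seed) twice gives bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m, k = cfg.n_markers, cfg.n_subpops

    # ---- map: near-even allocation over 1A..7B, sorted positions per chrom
    per_chrom = np.full(len(CHROMOSOMES), m // len(CHROMOSOMES))
    per_chrom[: m % len(CHROMOSOMES)] += 1
    chrom_col, pos_col = [], []
    for c, n_c in zip(CHROMOSOMES, per_chrom):
        chrom_col.extend([c] * n_c)
        pos_col.extend(np.sort(rng.uniform(0.0, cfg.map_length_cM, n_c)))
    width = len(str(m))
    ids = [f"M{i:0{width}d}" for i in range(m)]
    is_pav = rng.random(m) < cfg.frac_pav

    # ---- per-subpop allele-1 frequencies
    p0 = rng.uniform(*cfg.ancestral_freq_range, m)
    fst = np.broadcast_to(np.atleast_1d(cfg.fst_like_differentiation), (k,)).astype(float)
    freqs = _bn_freqs(rng, p0, fst)
    for idx, f_hi in cfg.high_divergence.items():
        a = p0[idx] * (1 - f_hi) / f_hi
        b = (1 - p0[idx]) * (1 - f_hi) / f_hi
        freqs[idx, :] = rng.beta(a, b, size=k)

    # ---- planted SP-private runs (override frequencies on consecutive markers)
    order = sorted(
        range(m), key=lambda i: (CHROMOSOMES.index(chrom_col[i]), pos_col[i], ids[i])
    )
    for run in cfg.private_runs:
        if not 0 <= run.subpop < k:
            raise ValueError(f"private run subpop {run.subpop} out of range")
        cands = [
            i for i in order
            if chrom_col[i] == run.chromosome and pos_col[i] >= run.start_cM
        ]
        if len(cands) < run.n_markers:
            raise ValueError(
                f"not enough markers on {run.chromosome} past {run.start_cM} cM"
            )
        chosen = cands[: run.n_markers]
        # compress the run into a tight span (a haplotype block is sub-cM on
        # the consensus map); capped so the run stays contiguous in map order
        span = run.span_cM
        if len(cands) > run.n_markers:
            span = min(span, 0.9 * (pos_col[cands[run.n_markers]] - run.start_cM))
        step = span / max(run.n_markers - 1, 1)
        for j, i in enumerate(chosen):
            pos_col[i] = run.start_cM + j * step
            freqs[i, :] = 1.0
            freqs[i, run.subpop] = 0.0

    markers = pd.DataFrame(
        {
            "chromosome": chrom_col,
            "position_cM": pos_col,
            "marker_class": np.where(is_pav, "PAV", "SNP"),
        },
        index=pd.Index(ids, name="marker_id"),
    )

    # ---- genotypes: names, home subpops, admixture, calls
    n = cfg.n_genotypes
    names = [f"L{i + 1:03d}" for i in range(cfg.n_landraces)] + [
        f"C{i + 1:03d}" for i in range(n - cfg.n_landraces)
    ]
    is_landrace = pd.Series(
        [g.startswith("L") for g in names], index=names, name="is_landrace"
    )
    if k >= 2:
        n_land_sp = max(1, math.ceil(k * 0.6)) if cfg.n_landraces else 0
        n_land_sp = min(n_land_sp, k - 1) if cfg.n_landraces < n else n_land_sp
        land_sps = list(range(n_land_sp)) or list(range(k))
        mod_sps = list(range(n_land_sp, k)) or list(range(k))
    else:
        land_sps = mod_sps = [0]
    home = np.empty(n, dtype=int)
    for i in range(cfg.n_landraces):
        home[i] = land_sps[i % len(land_sps)]
    for j, i in enumerate(range(cfg.n_landraces, n)):
        home[i] = mod_sps[j % len(mod_sps)]

    alpha = np.full((n, k), cfg.admixture_background)
    alpha[np.arange(n), home] = cfg.admixture_concentration
    q = np.empty((n, k))
    for i in range(n):
        q[i] = rng.dirichlet(alpha[i])

    pg = q @ freqs.T                       # n x m per-genotype allele-1 freq
    draw = rng.random((n, m)) < pg         # inbred: one draw per line/marker

    # SNP ref/alt letters
    bases = np.array(list("ACGT"))
    ref_alt = np.empty((m, 2), dtype="<U1")
    for j in range(m):
        ref_alt[j] = rng.choice(bases, size=2, replace=False)

    calls = np.empty((n, m), dtype=object)
    pav_cols = np.where(is_pav)[0]
    snp_cols = np.where(~is_pav)[0]
    for j in pav_cols:
        calls[:, j] = np.where(draw[:, j], "1", "0")
    for j in snp_cols:
        calls[:, j] = np.where(draw[:, j], ref_alt[j, 1], ref_alt[j, 0])
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        calls[miss] = np.nan

    sp_labels = [f"SP{s + 1}" for s in range(k)]
    panel = MarkerPanel(
        markers, pd.DataFrame(calls, index=names, columns=markers.index)
    )
    return PanelSim(
        panel=panel,
        q=pd.DataFrame(q, index=names, columns=sp_labels),
        subpop_freqs=pd.DataFrame(freqs, index=markers.index, columns=sp_labels),
        ancestral_freq=pd.Series(p0, index=markers.index, name="ancestral_freq"),
        home_subpop=pd.Series(home, index=names, name="home_subpop"),
        is_landrace=is_landrace,
    )


def between_subpop_spread(freqs: pd.DataFrame) -> pd.Series:
    """Per-marker max-minus-min allele frequency across subpopulations."""
    return freqs.max(axis=1) - freqs.min(axis=1)


# --------------------------------------------------------------------------
# field-trial simulation
# --------------------------------------------------------------------------

@dataclass
class QtlSpec:
    """One planted additive QTL: ``effect`` trait units per dosage allele."""

    marker_id: str
    trait: str
    effect: float
    years: tuple[int, ...] | None = None   # None = active every year


@dataclass
class TrialConfig:
    n_years: int = 3
    first_year: int = 2013
    tests_per_check: int = 5               # the 1:5 check:test ratio
    n_checks: int = 2
    check_names: tuple[str, ...] = ("Avispa", "Euroduro")
    # scalar = scale factor on the per-trait defaults; mapping = absolute SDs
    row_sd: float | dict = 0.4
    col_sd: float | dict = 0.4
    residual_sd: float | dict = 1.0
    polygenic_sd: float | dict = 0.0
    baselines: dict | None = None
    incident_par_daily: float = 12.0
    emergence_day: int = 20
    seed: int = 0

    def resolved(self):
        base = dict(DEFAULT_BASELINES)
        if self.baselines:
            base.update(self.baselines)

        def sds(v, defaults):
            if np.isscalar(v):
                return {t: float(v) * s for t, s in defaults.items()}
            return _per_trait(v, defaults)

        return (
            base,
            sds(self.row_sd, DEFAULT_RESIDUAL_SD),
            sds(self.col_sd, DEFAULT_RESIDUAL_SD),
            sds(self.residual_sd, DEFAULT_RESIDUAL_SD),
            sds(self.polygenic_sd, DEFAULT_GENETIC_SD),
        )


@dataclass
class TrialSim:
    records: list[PlotRecord]
    truth_plot: pd.DataFrame          # realized per-plot trait targets (tidy)
    genetic_values: dict[int, pd.DataFrame]   # year -> genotype x trait
    qtls: list[QtlSpec]
    config: TrialConfig


def serpentine_layout(n_plots: int) -> list[tuple[int, int]]:
    """(row, col) for each plot of a near-square serpentine-filled grid."""
    ncols = math.ceil(math.sqrt(n_plots))
    out = []
    for k in range(n_plots):
        r, j = divmod(k, ncols)
        out.append((r, j if r % 2 == 0 else ncols - 1 - j))
    return out


def _invert_plot(targets: dict[str, float], tcfg: TrialConfig) -> dict:
    """Raw measurements whose derived traits equal the (realized) targets.

    Returns the PlotRecord field dict plus the realized trait values
    (phenology rounded to whole days; ratio traits recomputed).
    """
    t = dict(targets)
    # phenology: whole days, each period at least one day
    d_eh = max(1, round(t["D_EH"]))
    d_ha = max(1, round(t["D_HA"]))
    d_am = max(1, round(t["D_AM"]))
    gs11 = tcfg.emergence_day
    gs55, gs65 = gs11 + d_eh, gs11 + d_eh + d_ha
    gs87 = gs65 + d_am
    t["D_EH"], t["D_HA"], t["D_AM"] = float(d_eh), float(d_ha), float(d_am)

    spacing = 0.15
    spikes = t["NS"] * 1.0 * spacing
    grains = t["NGS"] * spikes
    grain_mass = grains * t["W"] / 1000.0
    total_mass = grain_mass / t["HI"]
    t["DM_M"] = total_mass / (1.0 * spacing)
    t["GFR"] = t["W"] / t["D_AM"]

    # PAR: constant IPAR fraction per period, samples straddling each period
    # so integer-day interpolation returns the period constant exactly
    inc = tcfg.incident_par_daily
    par_samples: list[ParSample] = []
    realized = {}
    for name, a, b in (
        ("cPAR_EH", gs11, gs55), ("cPAR_HA", gs55, gs65), ("cPAR_AM", gs65, gs87),
    ):
        d = b - a
        f = float(np.clip(t[name] / (inc * d), 0.001, 0.97))
        realized[name] = f * inc * d
        par_i = 2000.0
        par_r = 0.03 * par_i
        par_t = par_i * (0.97 - f)
        days = [a - 0.25]
        day = a - 0.25 + 21.0
        while day < b - 0.75 - 1.0:
            days.append(day)
            day += 21.0
        days.append(b - 0.75)
        par_samples.extend(ParSample(dd, par_i, par_t, par_r) for dd in days)
    t.update(realized)
    t["RUE_EA"] = t["DM_A"] / (t["cPAR_EH"] + t["cPAR_HA"])
    t["RUE_AM"] = (t["DM_M"] - t["DM_A"]) / t["cPAR_AM"]

    ga_const = t["GA_90d"] / 90.0
    ga_samples = [GaSample(gs11 + d, ga_const) for d in range(0, 99, 14)]

    fields = dict(
        gs11=gs11, gs55=gs55, gs65=gs65, gs87=gs87,
        par_samples=par_samples, incident_par_daily=inc,
        dm_a_sample_g=t["DM_A"] * 0.5 * spacing,
        ta_anthesis=28.0, tc_anthesis=(28.0 - t["CTD_A"],) * 3,
        ta_milky=30.0, tc_milky=(30.0 - t["CTD_Mi"],) * 3,
        ga_samples=ga_samples,
        spikes=spikes, grains=grains,
        grain_mass_g=grain_mass, total_mass_g=total_mass,
        subsample_mass_g=10.0, subsample_grain_count=10_000.0 / t["W"],
        ph_cm=(t["PH"],) * 3, pl_cm=(t["PL"],) * 3,
        plot_yield_kg=t["Yield"] * 3.6 / 10_000.0,
        plot_area_m2=3.6, moisture_factor=1.0,
        row_spacing_m=spacing,
    )
    return fields, t


def simulate_trials(
    panel: MarkerPanel, qtls: list[QtlSpec], tcfg: TrialConfig
) -> TrialSim:
    """Generate the augmented-design plot records for every trial year."""
    baselines, row_sds, col_sds, res_sds, gen_sds = tcfg.resolved()
    for q_ in qtls:
        if q_.trait in DERIVED_TRAITS:
            raise ValueError(
                f"QTL trait {q_.trait!r} is a derived ratio trait; plant on one "
                f"of {PRIMARY_TRAITS}"
            )
        if q_.trait not in ALL_TRAITS:
            raise ValueError(f"unknown trait {q_.trait!r}")
        if q_.marker_id not in panel.marker_ids:
            raise ValueError(f"QTL marker {q_.marker_id!r} not in panel")

    rng = np.random.default_rng(tcfg.seed)
    genotypes = list(panel.genotypes)
    n_test = len(genotypes)
    years = [tcfg.first_year + i for i in range(tcfg.n_years)]

    dose = panel.dosage()
    dose = dose.fillna(dose.mean(axis=0))

    poly = {
        t: rng.normal(0.0, gen_sds[t], n_test) if gen_sds[t] > 0 else np.zeros(n_test)
        for t in PRIMARY_TRAITS
    }

    records: list[PlotRecord] = []
    truth_rows = []
    genetic_values: dict[int, pd.DataFrame] = {}
    for year in years:
        gv = pd.DataFrame(
            {t: baselines[t] + poly[t] for t in PRIMARY_TRAITS}, index=genotypes
        )
        for q_ in qtls:
            if q_.years is None or year in q_.years:
                gv[q_.trait] += q_.effect * dose[q_.marker_id].to_numpy()

        # plot sequence: a check after every `tests_per_check` test entries
        entries: list[tuple[str, bool]] = []
        check_i = 0
        for i, g in enumerate(genotypes):
            entries.append((g, False))
            if (i + 1) % tcfg.tests_per_check == 0:
                entries.append(
                    (tcfg.check_names[check_i % tcfg.n_checks], True)
                )
                check_i += 1
        if n_test % tcfg.tests_per_check != 0:
            entries.append((tcfg.check_names[check_i % tcfg.n_checks], True))

        layout = serpentine_layout(len(entries))
        n_rows = max(r for r, _ in layout) + 1
        n_cols = max(c for _, c in layout) + 1
        row_eff = {
            t: rng.normal(0.0, row_sds[t], n_rows) if row_sds[t] > 0 else np.zeros(n_rows)
            for t in PRIMARY_TRAITS
        }
        col_eff = {
            t: rng.normal(0.0, col_sds[t], n_cols) if col_sds[t] > 0 else np.zeros(n_cols)
            for t in PRIMARY_TRAITS
        }

        for plot_no, ((g, is_check), (r, c)) in enumerate(zip(entries, layout), 1):
            targets = {}
            for t in PRIMARY_TRAITS:
                base = baselines[t] if is_check else gv.at[g, t]
                eps = rng.normal(0.0, res_sds[t]) if res_sds[t] > 0 else 0.0
                targets[t] = base + row_eff[t][r] + col_eff[t][c] + eps
            targets["HI"] = float(np.clip(targets["HI"], 0.05, 0.95))
            fields, realized = _invert_plot(targets, tcfg)
            records.append(
                PlotRecord(
                    year=year, plot=plot_no, row=r, col=c,
                    genotype=g, is_check=is_check, **fields,
                )
            )
            for t in ALL_TRAITS:
                truth_rows.append(
                    {
                        "year": year, "plot": plot_no, "genotype": g,
                        "is_check": is_check, "trait": t, "value": realized[t],
                    }
                )
        genetic_values[year] = gv

    return TrialSim(
        records=records,
        truth_plot=pd.DataFrame(truth_rows),
        genetic_values=genetic_values,
        qtls=qtls,
        config=tcfg,
    )


def write_truth_json(sim: TrialSim, path) -> None:
    baselines, row_sds, col_sds, res_sds, gen_sds = sim.config.resolved()
    payload = {
        "qtls": [asdict(q_) for q_ in sim.qtls],
        "baselines": baselines,
        "row_sd": row_sds,
        "col_sd": col_sds,
        "residual_sd": res_sds,
        "polygenic_sd": gen_sds,
        "genetic_values": {
            str(y): gv.round(10).to_dict(orient="index")
            for y, gv in sim.genetic_values.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
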