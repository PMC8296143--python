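"""Calibration and recovery studies over the synthetic panel.

These are the package's standing experiments: type-I-error calibration of
the structure-aware scan against a confounded null (with the naive
unstructured scan as the inflation baseline), power for a planted 1-SD
additive QTL, and the end-to-end round trip from generator ground truth
(planted QTLs and a subpopulation-private haplotype run) through trait
derivation, BLUPs, the GWAS scan, hotspot chaining and haplotype-block
calling.  Problem sizes follow the emulated study design (300-genotype
panels for the calibration/power studies; a 150-genotype, three-year trial
for the round trip) and keep every study in the minutes range on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth, traits, blup, gwas, hotspots, haplotypes, structure

#: structure effect on the confounded trait, one coefficient per subpopulation
_STRUCT_BETA = np.array([3.0, 1.0, -2.0, 0.5, -1.5])


def _structured_panel(seed: int, n_markers: int) -> synth.PanelSim:
    cfg = synth.PanelConfig(
        n_genotypes=300, n_landraces=150, n_markers=n_markers,
        fst_like_differentiation=0.15, missing_rate=0.03, seed=seed,
    )
    return synth.simulate_panel(cfg)


def type_one_error_study(seed: int, n_markers: int = 2200) -> dict:
    """Empirical type-I error at alpha = 0.05 under a confounded null.

    The trait is a pure function of the membership coefficients plus iid
    noise — no marker is causal — so every rejection is a false positive.
    The same phenotype is scanned with the PCA + K model and with a naive
    unstructured regression.
    """
    sim = _structured_panel(seed, n_markers)
    panel, rep = gwas.qc_markers(sim.panel)
    K = gwas.kinship(panel)
    pcs = gwas.genotype_pcs(panel, 6)
    rng = np.random.default_rng(seed + 1)
    y = pd.Series(
        sim.q.to_numpy() @ _STRUCT_BETA + rng.normal(0.0, 1.0, len(sim.q)),
        index=sim.q.index,
    )
    scan = gwas.mlm_scan(y, panel, pcs, K)
    naive = gwas.mlm_scan(y, panel, None, None)
    n = len(scan)
    return {
        "n_tests": n,
        "mlm_type1": float((scan["p"] < 0.05).mean()),
        "naive_type1": float((naive["p"] < 0.05).mean()),
        "binomial_3sd": 3.0 * float(np.sqrt(0.05 * 0.95 / n)),
    }


def power_study(seed: int, n_markers: int = 800, n_reps: int = 100) -> dict:
    """Detection rate for a planted additive QTL of one phenotypic SD.

    Each replicate redraws the structured + iid part of the phenotype and
    adds ``dosage * sd(y)`` at a fixed common marker; detection means
    -log10 p >= 3 in the PCA + K scan.  A second part plants the same QTL
    in two trial years and checks that the two per-year MTAs chain into a
    called QTL hotspot.
    """
    sim = _structured_panel(seed, n_markers)
    panel, _ = gwas.qc_markers(sim.panel)
    K = gwas.kinship(panel)
    pcs = gwas.genotype_pcs(panel, 6)
    dose = panel.dosage()
    dose = dose.fillna(dose.mean())
    marker = dose.var().idxmax()
    target = panel.subset_markers([marker])

    rng = np.random.default_rng(seed + 2)
    hits = 0
    for _ in range(n_reps):
        base = sim.q.to_numpy() @ _STRUCT_BETA + rng.normal(0.0, 1.0, len(sim.q))
        y = pd.Series(base, index=panel.genotypes)
        y = y + dose[marker] * float(y.std())
        scan = gwas.mlm_scan(y, target, pcs, K)
        hits += bool(scan["neg_log10_p"].iloc[0] >= 3.0)

    # two-year recovery: full scans, MTA calling, chaining, hotspot rule
    scans = {}
    for year in (2013, 2014):
        base = sim.q.to_numpy() @ _STRUCT_BETA + rng.normal(0.0, 1.0, len(sim.q))
        y = pd.Series(base, index=panel.genotypes)
        y = y + dose[marker] * float(y.std())
        scans[("Yield", str(year))] = gwas.mlm_scan(y, panel, pcs, K)
    mtas = gwas.call_mtas(scans)
    hs = hotspots.call_hotspots(hotspots.chain_blocks(mtas))
    recovered = any(
        marker in set(h.members["marker_id"]) and len(h.years) >= 2 for h in hs
    )
    return {
        "n_reps": n_reps,
        "power": hits / n_reps,
        "hotspot_recovered": bool(recovered),
        "marker": marker,
    }


def end_to_end_roundtrip(seed: int) -> dict:
    """Noise-free chain from generator truth to the haplotype block.

    A 150-genotype panel carries a 4-marker SP3-private haplotype run; a
    yield QTL sits on the first run marker and a grain-weight QTL a few
    markers away.  With all noise SDs at zero the derived traits must equal
    the truth table, per-year BLUPs must equal the planted genotypic
    values, the per-year scans must flag the causal markers, the MTAs must
    chain into a hotspot, and the private run must come back as one
    haplotype block differentiating SP3.
    """
    run = synth.SpPrivateRun(subpop=2, chromosome="2A", start_cM=40.0, n_markers=4)
    cfg = synth.PanelConfig(
        n_genotypes=150, n_landraces=90, n_markers=400, missing_rate=0.0,
        fst_like_differentiation=0.05, admixture_concentration=60.0,
        private_runs=[run], seed=seed,
    )
    sim = synth.simulate_panel(cfg)
    freqs = sim.subpop_freqs
    planted = list(
        freqs.index[
            (freqs["SP3"] == 0.0)
            & (freqs.drop(columns="SP3") == 1.0).all(axis=1)
        ]
    )
    qtl_marker = planted[0]
    w_marker = freqs.index[freqs.index.get_loc(planted[-1]) + 2]
    qtls = [
        synth.QtlSpec(qtl_marker, "Yield", 400.0),
        synth.QtlSpec(w_marker, "W", 3.0),
    ]
    tcfg = synth.TrialConfig(
        n_years=3, row_sd=0.0, col_sd=0.0, residual_sd=0.0, seed=seed + 3
    )
    trial = synth.simulate_trials(sim.panel, qtls, tcfg)

    # 1) trait derivation reproduces the truth table
    tt = traits.derive_trait_table(trial.records)
    merged = tt.merge(
        trial.truth_plot, on=["year", "plot", "genotype", "trait"],
        suffixes=("_d", "_t"),
    )
    scale = merged["value_t"].abs().clip(lower=1.0)
    trait_err = float(((merged["value_d"] - merged["value_t"]).abs() / scale).max())

    # 2) per-year BLUPs reproduce the planted genotypic values
    years = sorted(tt["year"].unique())
    blup_err = 0.0
    scans = {}
    K = gwas.kinship(sim.panel)
    pcs = gwas.genotype_pcs(sim.panel, 6)
    for trait_name in ("Yield", "W"):
        sub = tt[tt["trait"] == trait_name]
        for year in years:
            fit = blup.fit_augmented(sub[sub["year"] == year])
            truth = trial.genetic_values[year][trait_name]
            blup_err = max(
                blup_err, float((fit.blups[truth.index] - truth).abs().max())
            )
            scans[(trait_name, str(year))] = gwas.mlm_scan(
                fit.blups, sim.panel, pcs, K
            )

    # 3) MTAs at the causal markers in every year, chained into a hotspot
    mtas = gwas.call_mtas(scans)
    yield_hits = mtas[(mtas["trait"] == "Yield") & (mtas["marker_id"] == qtl_marker)]
    w_hits = mtas[(mtas["trait"] == "W") & (mtas["marker_id"] == w_marker)]
    hs = hotspots.call_hotspots(hotspots.chain_blocks(mtas))
    target_hs = [h for h in hs if qtl_marker in set(h.members["marker_id"])]

    # 4) the private haplotype run is recovered with SP3 differentiating
    hb_exact = False
    diff_sp = None
    linked_traits: tuple = ()
    if target_hs:
        h = target_hs[0]
        subpops = structure.assign_subpops(sim.q)
        calls = haplotypes.sp_allele_calls(sim.panel, subpops, h)
        hbs = haplotypes.define_hbs(calls, h)
        match = [hb for hb in hbs if set(planted) <= set(hb.marker_ids)]
        if match:
            hb = match[0]
            hb_exact = tuple(planted) == hb.marker_ids
            diff_sp = sorted(hb.diff_subpops)
            links = haplotypes.link_hb_traits(hbs, mtas, [h])
            linked_traits = tuple(
                sorted(links.loc[links["hb_id"] == hb.id, "trait"])
            )
    return {
        "trait_max_rel_err": trait_err,
        "blup_max_abs_err": blup_err,
        "n_years_yield_mta": int(yield_hits["scope"].nunique()),
        "n_years_w_mta": int(w_hits["scope"].nunique()),
        "hotspot_called": bool(target_hs),
        "hb_run_exact": bool(hb_exact),
        "hb_diff_subpops": diff_sp,
        "hb_linked_traits": linked_traits,
    }
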