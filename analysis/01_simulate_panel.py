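#!/usr/bin/env python
"""Simulate the diversity panel and the three-year augmented field trial.

Emulates the study design the pipeline targets: 372 inbred genotypes
(172 landraces + 200 modern cultivars) in five admixed subpopulations,
DArTseq-like PAV/SNP markers on the 14-chromosome cM map (scaled to 3,000
markers), and three years of a non-replicated augmented design with two
checks at a 1:5 check:test ratio.  Ground truth: ten additive QTLs on five
traits plus one SP3-private haplotype run on chromosome 2A (with a yield
QTL on its first marker).

Writes geno.tsv, map.tsv, q.tsv, plot_records.csv and truth.json under
<outdir>/synthetic/.
"""

import argparse
import json
from pathlib import Path

import durumpanel as dp
from durumpanel.records import write_records_csv
from durumpanel.synth import write_truth_json


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-markers", type=int, default=3000)
    args = ap.parse_args()
    out = args.outdir / "synthetic"
    out.mkdir(parents=True, exist_ok=True)

    run = dp.SpPrivateRun(subpop=2, chromosome="2A", start_cM=40.0, n_markers=5)
    cfg = dp.PanelConfig(
        n_genotypes=372, n_landraces=172, n_markers=args.n_markers,
        fst_like_differentiation=0.12, missing_rate=0.03,
        private_runs=[run], seed=args.seed,
    )
    sim = dp.simulate_panel(cfg)
    freqs = sim.subpop_freqs
    planted = list(
        freqs.index[(freqs["SP3"] == 0.0)
                    & (freqs.drop(columns="SP3") == 1.0).all(axis=1)]
    )
    dose = sim.panel.dosage()
    by_var = dose.var().sort_values(ascending=False).index
    qtl_markers = [m for m in by_var if m not in planted][:9]
    qtls = [
        dp.QtlSpec(planted[0], "Yield", 250.0),
        dp.QtlSpec(qtl_markers[0], "Yield", 180.0),
        dp.QtlSpec(qtl_markers[1], "W", 2.5),
        dp.QtlSpec(qtl_markers[2], "W", -2.0),
        dp.QtlSpec(qtl_markers[3], "NGS", 2.0),
        dp.QtlSpec(qtl_markers[4], "D_EH", 3.0),
        dp.QtlSpec(qtl_markers[5], "D_EH", -2.0, years=(2014, 2015)),
        dp.QtlSpec(qtl_markers[6], "PH", 8.0),
        dp.QtlSpec(qtl_markers[7], "HI", 0.03),
        dp.QtlSpec(qtl_markers[8], "CTD_A", 0.8),
    ]
    tcfg = dp.TrialConfig(n_years=3, seed=args.seed + 1, polygenic_sd=0.8)
    trial = dp.simulate_trials(sim.panel, qtls, tcfg)

    sim.panel.to_tsv(out / "geno.tsv")
    sim.panel.markers.rename(columns={"marker_class": "class"}).to_csv(
        out / "map.tsv", sep="\t"
    )
    sim.q.to_csv(out / "q.tsv", sep="\t", float_format="%.12g")
    write_records_csv(trial.records, out / "plot_records.csv")
    write_truth_json(trial, out / "truth.json")
    meta = {
        "planted_private_run": planted,
        "qtls": [
            {"marker": q.marker_id, "trait": q.trait, "effect": q.effect,
             "years": q.years}
            for q in qtls
        ],
    }
    (out / "design.json").write_text(json.dumps(meta, indent=1))

    n_assigned = int((sim.q.max(axis=1) > 0.80).sum())
    print(f"panel: {sim.panel.n_genotypes} genotypes "
          f"({cfg.n_landraces} landraces), {sim.panel.n_markers} markers "
          f"({(sim.panel.markers['marker_class'] == 'PAV').sum()} PAV)")
    print(f"assigned to a subpopulation at q > 0.80: {n_assigned}")
    print(f"trial: {len(trial.records)} plot-years over "
          f"{tcfg.n_years} years "
          f"({sum(r.is_check for r in trial.records)} check plots)")
    print(f"planted SP3-private run on 2A: {planted}")
    print(f"outputs in {out}/")


if __name__ == "__main__":
    main()
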