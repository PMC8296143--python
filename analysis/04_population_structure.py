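#!/usr/bin/env python
"""Relate trait variation to the genetic structure of the panel.

Assigns genotypes to subpopulations at q > 0.80, regresses across-year
genotype means on the membership coefficients, compares landraces vs
modern cultivars and the five subpopulations with the partitioned ANOVA
(Tukey-Kramer letters), and summarizes trait covariation with PCA, Ward
clustering and Pearson correlations.
"""

import argparse
from pathlib import Path

import pandas as pd

import durumpanel as dp
from durumpanel.structure import ADMIXED, linkage_to_newick


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir

    q = pd.read_csv(out / "synthetic" / "q.tsv", sep="\t", index_col=0)
    tt = pd.read_csv(out / "trait_table.csv")
    means = (
        tt[~tt["is_check"]]
        .groupby(["genotype", "trait"])["value"].mean()
        .unstack()[dp.ALL_TRAITS]
    )

    subpops = dp.assign_subpops(q)
    subpops.to_frame().to_csv(out / "subpop_assignment.csv")
    n_assigned = int((subpops != ADMIXED).sum())

    r2 = dp.structure_regression(means, q)
    r2.to_frame().to_csv(out / "structure_r2.csv")

    landrace = pd.Series(
        ["landrace" if g.startswith("L") else "modern" for g in means.index],
        index=means.index,
    )
    rows_lm, rows_sp = [], []
    for trait in dp.ALL_TRAITS:
        cmp_lm = dp.partitioned_anova(means[trait], landrace, trait=trait)
        rows_lm.append(
            cmp_lm.table.assign(trait=trait, F=cmp_lm.f_value, P=cmp_lm.p_value)
        )
        assigned = means.loc[subpops[subpops != ADMIXED].index, trait]
        cmp_sp = dp.partitioned_anova(
            assigned, subpops[subpops != ADMIXED], trait=trait
        )
        rows_sp.append(
            cmp_sp.table.assign(trait=trait, F=cmp_sp.f_value, P=cmp_sp.p_value)
        )
    pd.concat(rows_lm).to_csv(out / "group_comparison_landrace_modern.csv",
                              index=False)
    pd.concat(rows_sp).to_csv(out / "group_comparison_subpops.csv", index=False)

    assigned_means = means.loc[subpops[subpops != ADMIXED].index]
    pca = dp.trait_pca(assigned_means)
    pca.scores.round(4).to_csv(out / "pca_scores.csv")
    pca.loadings.round(4).to_csv(out / "pca_loadings.csv")
    pca.explained.round(4).to_frame().to_csv(out / "pca_explained.csv")

    link = dp.ward_cluster(means)
    (out / "ward_dendrogram.nwk").write_text(
        linkage_to_newick(link, list(means.dropna().index))
    )
    dp.pearson_matrix(means).round(3).to_csv(out / "trait_correlations.csv")

    print(f"{n_assigned} of {len(q)} genotypes assigned at q > 0.80 "
          f"({(subpops != ADMIXED).groupby(subpops).size().to_dict()})")
    print("\nstructure regression R^2 (top 5):")
    print(r2.sort_values(ascending=False).head().round(3).to_string())
    print("\nlandrace vs modern, Yield:")
    print(rows_lm[0].to_string(index=False))
    print(f"\nPCA: PC1 {pca.explained['PC1']:.1%}, PC2 {pca.explained['PC2']:.1%}"
          f" of assigned-genotype trait variance")


if __name__ == "__main__":
    main()
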