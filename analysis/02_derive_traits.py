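#!/usr/bin/env python
"""Derive the 21 agro-physiological traits from the raw plot records.

Reads <outdir>/synthetic/plot_records.csv, applies the trait-derivation
rules (phenology intervals, IPAR -> cumulated absorbed PAR, RUE, CTD,
GA_90d, yield components) and writes the tidy trait table.
"""

import argparse
from pathlib import Path

import durumpanel as dp
from durumpanel.records import read_records_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.outdir

    records = read_records_csv(out / "synthetic" / "plot_records.csv")
    tt = dp.derive_trait_table(records)
    tt.to_csv(out / "trait_table.csv", index=False)

    tests = tt[~tt["is_check"]]
    tests = tests.assign(landrace=tests["genotype"].str.startswith("L"))
    wide = tests.pivot_table(
        index="trait", columns="landrace", values="value", aggfunc="mean"
    ).rename(columns={True: "landraces", False: "modern"}).rename_axis(columns=None)
    print(f"{len(records)} plot records -> {len(tt)} trait values")
    print("\nmean by germplasm group (plot level):")
    print(wide.loc[dp.ALL_TRAITS].round(2).to_string())
    print(f"\nwrote {out / 'trait_table.csv'}")


if __name__ == "__main__":
    main()
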