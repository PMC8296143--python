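"""Published summary counts from the motivating durum-panel field study.

The genotype and phenotype data behind the original three-year evaluation
of the 372-entry Mediterranean durum panel were never deposited, so its
marker-level results cannot be recomputed; what *can* be checked are the
internal bookkeeping identities of its printed summary tables.  This module
stores those printed counts as data — the per-trait/per-year MTA table
(total and FDR-significant in parentheses in the original layout), the
marker inventory before and after QC, and the MTA census of the largest
QTL hotspot — together with the arithmetic that reconciles them.
"""

from __future__ import annotations

import pandas as pd

#: trait -> ((2013 total, 2013 fdr), (2014 ...), (2015 ...)) MTA counts
MTA_COUNTS = {
    "Yield":   ((25, 2), (17, 0), (19, 1)),
    "NS":      ((25, 3), (11, 0), (16, 1)),
    "NGS":     ((81, 14), (50, 23), (39, 14)),
    "W":       ((96, 39), (61, 29), (77, 33)),
    "HI":      ((11, 0), (15, 1), (30, 0)),
    "D_EH":    ((24, 0), (32, 7), (62, 7)),
    "D_HA":    ((20, 1), (29, 1), (29, 0)),
    "D_AM":    ((32, 0), (22, 1), (28, 2)),
    "GFR":     ((97, 28), (55, 0), (83, 29)),
    "PL":      ((33, 0), (27, 2), (52, 3)),
    "PH":      ((30, 3), (60, 3), (86, 7)),
    "DM_A":    ((21, 0), (9, 0), (32, 2)),
    "DM_M":    ((55, 1), (14, 0), (20, 1)),
    "CTD_A":   ((15, 0), (9, 0), (29, 2)),
    "CTD_Mi":  ((15, 0), (55, 7), (20, 1)),
    "cPAR_EH": ((21, 0), (15, 0), (26, 0)),
    "cPAR_HA": ((25, 0), (21, 0), (9, 0)),
    "cPAR_AM": ((19, 0), (45, 0), (40, 0)),
    "RUE_EA":  ((10, 0), (13, 0), (6, 0)),
    "RUE_AM":  ((48, 2), (7, 0), (9, 1)),
    "GA_90d":  ((26, 1), (12, 1), (26, 0)),
}

YEARS = (2013, 2014, 2015)
N_CHROMOSOMES = 14

#: printed overall MTA census and the largest hotspot's share of FDR MTAs
PRINTED_TOTAL_MTAS = 2046
PRINTED_FDR_MTAS = 273
HOTSPOT_2A2_FDR_MTAS = 177
HOTSPOT_2A2_MTAS = 427
N_HOTSPOTS = 144
MTAS_IN_HOTSPOTS = 1927

#: marker inventory: genotyped and retained after QC, split by class
MARKERS_GENOTYPED = {"PAV": 35837, "SNP": 10324}
PRINTED_MARKERS_GENOTYPED_TOTAL = 46161
MARKERS_POST_QC = {"PAV": 19030, "SNP": 4686}
PRINTED_MARKERS_POST_QC_TOTAL = 23716


def mta_count_frame() -> pd.DataFrame:
    """The per-trait/per-year MTA counts as a tidy frame."""
    rows = []
    for trait, per_year in MTA_COUNTS.items():
        for year, (n, n_fdr) in zip(YEARS, per_year):
            rows.append({"trait": trait, "year": year, "n": n, "n_fdr": n_fdr})
    return pd.DataFrame(rows)


def total_mtas() -> int:
    """Overall MTA count recomputed by summing the per-trait/per-year cells."""
    return int(mta_count_frame()["n"].sum())


def total_fdr_mtas() -> int:
    return int(mta_count_frame()["n_fdr"].sum())


def mtas_per_chromosome_mean() -> float:
    """Average MTAs per chromosome over the 14 durum chromosomes."""
    return total_mtas() / N_CHROMOSOMES


def hotspot_2a2_fdr_share_percent() -> float:
    """Percent of all FDR-significant MTAs that fall in hotspot 2A.2."""
    return 100.0 * HOTSPOT_2A2_FDR_MTAS / PRINTED_FDR_MTAS


def markers_genotyped_total() -> int:
    return sum(MARKERS_GENOTYPED.values())


def markers_post_qc_total() -> int:
    return sum(MARKERS_POST_QC.values())
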