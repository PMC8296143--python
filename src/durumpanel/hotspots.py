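"""QTL hotspots: LD-window chaining of marker-trait associations.

MTAs on one chromosome are chained into LD blocks by single linkage at the
panel's LD-decay distance (default 1 cM, transitive closure: a chain of
<=1 cM steps joins one block, so a block may span more than the window).
A block qualifies as a QTL hotspot when it holds at least two MTAs from at
least two distinct trial years; hotspots are numbered per chromosome in
ascending map order as ``<chromosome>.<ordinal>`` (e.g. ``2A.2``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import chromosome_sort_key

log = logging.getLogger(__name__)

ACROSS_SCOPE = "across"


@dataclass
class LdBlock:
    chromosome: str
    start_cM: float
    end_cM: float
    members: pd.DataFrame      # MTA rows, sorted by position


@dataclass
class Hotspot:
    id: str
    chromosome: str
    start_cM: float
    end_cM: float
    members: pd.DataFrame
    years: tuple[str, ...]
    traits: tuple[str, ...]
    n_fdr_significant: int


def _canonical(mtas: pd.DataFrame) -> pd.DataFrame:
    """Drop unpositioned MTAs and sort canonically (chrom, cM, marker, trait)."""
    ok = mtas["position_cM"].notna() & mtas["chromosome"].notna()
    dropped = int((~ok).sum())
    if dropped:
        log.warning("excluding %d MTAs without a map position", dropped)
    out = mtas[ok].copy()
    out["_crank"] = out["chromosome"].map(chromosome_sort_key)
    out = out.sort_values(
        ["_crank", "position_cM", "marker_id", "trait", "scope"]
    ).drop(columns="_crank")
    return out.reset_index(drop=True)


def chain_blocks(mtas: pd.DataFrame, window_cM: float = 1.0) -> list[LdBlock]:
    """Single-linkage chaining of MTAs per chromosome.

    Two MTAs join one block iff their positions differ by at most
    ``window_cM``, with transitive closure; blocks are maximal and partition
    the positioned MTAs of each chromosome.
    """
    mtas = _canonical(mtas)
    blocks: list[LdBlock] = []
    for chrom, sub in mtas.groupby("chromosome", sort=False):
        pos = sub["position_cM"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > window_cM) + 1
        for piece in np.split(np.arange(len(sub)), breaks):
            mem = sub.iloc[piece]
            blocks.append(
                LdBlock(
                    chromosome=chrom,
                    start_cM=float(mem["position_cM"].min()),
                    end_cM=float(mem["position_cM"].max()),
                    members=mem.reset_index(drop=True),
                )
            )
    blocks.sort(key=lambda b: (chromosome_sort_key(b.chromosome), b.start_cM))
    return blocks


def call_hotspots(
    blocks: list[LdBlock], count_across_scope: bool = False
) -> list[Hotspot]:
    """Blocks holding >=2 MTAs from >=2 distinct years become hotspots.

    MTAs from the across-years scan do not count toward the distinct-year
    requirement unless ``count_across_scope`` is set (they are still listed
    as members).  Qualifying blocks are numbered per chromosome in ascending
    cM order.
    """
    hotspots: list[Hotspot] = []
    ordinal: dict[str, int] = {}
    for b in blocks:
        scopes = b.members["scope"].astype(str)
        year_scopes = scopes if count_across_scope else scopes[scopes != ACROSS_SCOPE]
        if len(b.members) < 2 or year_scopes.nunique() < 2:
            continue
        ordinal[b.chromosome] = ordinal.get(b.chromosome, 0) + 1
        hotspots.append(
            Hotspot(
                id=f"{b.chromosome}.{ordinal[b.chromosome]}",
                chromosome=b.chromosome,
                start_cM=b.start_cM,
                end_cM=b.end_cM,
                members=b.members,
                years=tuple(sorted(year_scopes.unique())),
                traits=tuple(sorted(b.members["trait"].unique())),
                n_fdr_significant=int(b.members["fdr_significant"].sum()),
            )
        )
    return hotspots


def hotspot_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = [
        {
            "hotspot_id": h.id,
            "chromosome": h.chromosome,
            "start_cM": h.start_cM,
            "end_cM": h.end_cM,
            "n_mtas": len(h.members),
            "years": ";".join(h.years),
            "traits": ";".join(h.traits),
            "n_fdr_significant": h.n_fdr_significant,
        }
        for h in hotspots
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "hotspot_id", "chromosome", "start_cM", "end_cM",
            "n_mtas", "years", "traits", "n_fdr_significant",
        ],
    )
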