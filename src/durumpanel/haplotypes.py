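"""Subpopulation-differentiated haplotype blocks within QTL hotspots.

For each marker inside a hotspot's interval the modal (major) allele and
its frequency are computed per subpopulation over the assigned (q > 0.8)
genotypes; a major allele below the 60 % frequency threshold is reported as
NA.  A marker *differentiates* when at least one subpopulation's called
allele differs from the called allele of every other called subpopulation;
a haplotype block (HB) is a maximal run of consecutive differentiating
markers sharing the same differentiating-subpopulation set.  HBs inherit
trait links from MTAs on their markers, falling back to the hotspot's
traits (flagged indirect) when none of their own markers carries an MTA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MarkerPanel
from .hotspots import Hotspot
from .structure import ADMIXED

log = logging.getLogger(__name__)

NA_TOKEN = "NA"


@dataclass
class HaplotypeBlock:
    id: str                       # "<hotspot>.HB<ordinal>"
    hotspot_id: str
    marker_ids: tuple[str, ...]   # contiguous in map order within the hotspot
    start_cM: float
    end_cM: float
    diff_subpops: frozenset[str]
    haplotypes: dict[str, str]    # SP -> allele string ("/" joined, NA kept)
    mean_freq: dict[str, float]   # SP -> mean major-allele frequency


def hotspot_markers(panel: MarkerPanel, hotspot: Hotspot) -> list[str]:
    m = panel.markers
    inside = (
        (m["chromosome"] == hotspot.chromosome)
        & (m["position_cM"] >= hotspot.start_cM)
        & (m["position_cM"] <= hotspot.end_cM)
    )
    return list(m.index[inside])   # panel is map-sorted


def sp_allele_calls(
    panel: MarkerPanel,
    subpops: pd.Series,
    hotspot: Hotspot,
    min_freq: float = 0.60,
) -> pd.DataFrame:
    """Major allele and frequency per marker x subpopulation.

    ``subpops`` is the assignment from the membership step (admixed
    genotypes are ignored).  The call is NA when the major-allele frequency
    among non-missing calls is below ``min_freq`` or no calls exist.  Modal
    ties break to the lexicographically smaller allele (their frequency can
    never reach a majority threshold anyway).
    """
    sps = sorted(set(subpops) - {ADMIXED})
    rows = []
    mids = hotspot_markers(panel, hotspot)
    if not mids:
        warnings.warn(f"hotspot {hotspot.id} spans no panel markers", stacklevel=2)
    for sp in sps:
        members = subpops.index[(subpops == sp) & subpops.index.isin(panel.genotypes)]
        if len(members) == 0:
            warnings.warn(f"no assigned genotypes in {sp}", stacklevel=2)
        for mid in mids:
            allele, freq = NA_TOKEN, np.nan
            if len(members):
                col = panel.calls.loc[members, mid].dropna()
                if len(col):
                    counts = col.value_counts()
                    top = counts.max()
                    allele = sorted(counts.index[counts == top])[0]
                    freq = float(top / len(col))
            called = bool(np.isfinite(freq) and freq >= min_freq)
            rows.append(
                {
                    "marker_id": mid,
                    "position_cM": float(panel.markers.at[mid, "position_cM"]),
                    "subpop": sp,
                    "allele": allele if called else NA_TOKEN,
                    "raw_allele": allele,
                    "freq": freq,
                    "called": called,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id", "position_cM", "subpop",
            "allele", "raw_allele", "freq", "called",
        ],
    )


def _diff_set(calls_at_marker: pd.DataFrame) -> frozenset[str]:
    """Subpopulations whose called allele differs from every other called SP."""
    called = calls_at_marker[calls_at_marker["called"]]
    if len(called) < 2:
        return frozenset()
    out = set()
    for _, r in called.iterrows():
        others = called[called["subpop"] != r["subpop"]]
        if (others["raw_allele"] != r["raw_allele"]).all():
            out.add(r["subpop"])
    return frozenset(out)


def define_hbs(
    sp_calls: pd.DataFrame,
    hotspot: Hotspot,
    diff_threshold: float = 0.60,
    min_markers: int = 1,
) -> list[HaplotypeBlock]:
    """Maximal runs of consecutive differentiating markers.

    The calling threshold can be re-applied here (``diff_threshold``), so a
    stricter cutoff than the one used in ``sp_allele_calls`` never creates
    new differentiating markers.  Runs shorter than ``min_markers`` are
    dropped.
    """
    if sp_calls.empty:
        return []
    calls = sp_calls.copy()
    calls["called"] = calls["freq"].ge(diff_threshold).fillna(False)
    calls["allele"] = calls["raw_allele"].where(calls["called"], NA_TOKEN)
    sps = sorted(calls["subpop"].unique())
    order = (
        calls[["marker_id", "position_cM"]]
        .drop_duplicates()
        .sort_values(["position_cM", "marker_id"])["marker_id"]
        .tolist()
    )
    per_marker = {
        mid: _diff_set(calls[calls["marker_id"] == mid]) for mid in order
    }

    blocks: list[HaplotypeBlock] = []
    run: list[str] = []
    run_set: frozenset[str] = frozenset()

    def flush():
        nonlocal run
        if len(run) >= min_markers and run_set:
            sub = calls[calls["marker_id"].isin(run)]
            sub = sub.set_index(["marker_id", "subpop"])
            haps, mfreq = {}, {}
            for sp in sps:
                alleles = [sub.loc[(m, sp), "allele"] for m in run]
                freqs = [sub.loc[(m, sp), "freq"] for m in run]
                haps[sp] = "/".join(alleles)
                finite = [f for f in freqs if np.isfinite(f)]
                mfreq[sp] = float(np.mean(finite)) if finite else np.nan
            pos = [
                float(calls.loc[calls["marker_id"] == m, "position_cM"].iloc[0])
                for m in run
            ]
            blocks.append(
                HaplotypeBlock(
                    id=f"{hotspot.id}.HB{len(blocks) + 1}",
                    hotspot_id=hotspot.id,
                    marker_ids=tuple(run),
                    start_cM=min(pos),
                    end_cM=max(pos),
                    diff_subpops=run_set,
                    haplotypes=haps,
                    mean_freq=mfreq,
                )
            )
        run = []

    for mid in order:
        dset = per_marker[mid]
        if not dset:
            flush()
            continue
        if run and dset == run_set:
            run.append(mid)
        else:
            flush()
            run, run_set = [mid], dset
    flush()
    return blocks


def link_hb_traits(
    hbs: list[HaplotypeBlock], mtas: pd.DataFrame, hotspots: list[Hotspot]
) -> pd.DataFrame:
    """Trait links per HB: direct (MTA on an HB marker) or inherited.

    An HB whose markers carry no MTA inherits its hotspot's traits, flagged
    ``direct=False``.
    """
    hs_traits = {h.id: h.traits for h in hotspots}
    rows = []
    for hb in hbs:
        hit = mtas[mtas["marker_id"].isin(hb.marker_ids)]
        if not hit.empty:
            for trait in sorted(hit["trait"].unique()):
                rows.append({"hb_id": hb.id, "trait": trait, "direct": True})
        else:
            for trait in hs_traits.get(hb.hotspot_id, ()):
                rows.append({"hb_id": hb.id, "trait": trait, "direct": False})
    return pd.DataFrame(rows, columns=["hb_id", "trait", "direct"])


def allele_matrix(sp_calls: pd.DataFrame) -> pd.DataFrame:
    """Marker x subpopulation matrix of called major alleles (NA kept), with
    a companion frequency matrix — the published-figure layout."""
    alleles = sp_calls.pivot(index="marker_id", columns="subpop", values="allele")
    freqs = sp_calls.pivot(index="marker_id", columns="subpop", values="freq")
    pos = sp_calls.drop_duplicates("marker_id").set_index("marker_id")["position_cM"]
    alleles.insert(0, "position_cM", pos)
    return alleles.join(freqs.round(3).add_suffix("_freq"))


def hb_table(hbs: list[HaplotypeBlock]) -> pd.DataFrame:
    rows = [
        {
            "hb_id": hb.id,
            "hotspot_id": hb.hotspot_id,
            "n_markers": len(hb.marker_ids),
            "start_cM": hb.start_cM,
            "end_cM": hb.end_cM,
            "diff_subpops": ";".join(sorted(hb.diff_subpops)),
            **{f"hap_{sp}": h for sp, h in hb.haplotypes.items()},
        }
        for hb in hbs
    ]
    return pd.DataFrame(rows)
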