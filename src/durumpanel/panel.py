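"""Marker panel container for DArTseq-style genotype data.

The panel holds two marker classes side by side:

* PAV (presence/absence variants), dominant-scored and coded ``"1"``/``"0"``;
* SNPs, coded as single IUPAC letters.  The panel is an inbred (self-pollinated)
  collection, so SNP calls are expected to be homozygous bases (A/C/G/T);
  ambiguity letters are accepted on read and treated as heterozygous.

Markers carry a genetic-map location (chromosome ``1A``..``7B``, position in cM).
A numeric *dosage* view maps every call to ``{0, 1}`` (``0.5`` for a
heterozygote, ``NaN`` for missing): PAVs directly, SNPs by presence of the
per-marker minor allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Wheat A/B-genome chromosome names in canonical order.
CHROMOSOMES = [f"{n}{g}" for n in range(1, 8) for g in ("A", "B")]

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Homozygous IUPAC letters.
HOMOZYGOUS_BASES = frozenset("ACGT")

#: IUPAC ambiguity letters and the base pair each represents.
IUPAC_HET = {
    "M": ("A", "C"),
    "R": ("A", "G"),
    "W": ("A", "T"),
    "S": ("C", "G"),
    "Y": ("C", "T"),
    "K": ("G", "T"),
}

VALID_SNP_CALLS = HOMOZYGOUS_BASES | set(IUPAC_HET)
VALID_PAV_CALLS = frozenset({"0", "1"})

MISSING = "NA"


def chromosome_sort_key(chrom: str) -> int:
    try:
        return _CHROM_RANK[chrom]
    except KeyError:
        raise ValueError(f"unknown chromosome {chrom!r}") from None


@dataclass
class MarkerPanel:
    """Genotype calls plus a genetic map.

    Parameters
    ----------
    markers
        DataFrame indexed by marker id with columns ``chromosome``,
        ``position_cM`` and ``marker_class`` (``"PAV"``/``"SNP"``).
    calls
        DataFrame (genotypes x markers) of string calls; missing values as NaN.
    """

    markers: pd.DataFrame
    calls: pd.DataFrame
    _dosage: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"chromosome", "position_cM", "marker_class"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"markers frame must have columns {sorted(required)}")
        if list(self.calls.columns) != list(self.markers.index):
            self.calls = self.calls.reindex(columns=self.markers.index)
        if (self.markers["position_cM"] < 0).any():
            raise ValueError("map positions must be non-negative")
        unknown = set(self.markers["chromosome"]) - set(CHROMOSOMES)
        if unknown:
            raise ValueError(f"unknown chromosomes: {sorted(unknown)}")
        self.sort_map()

    # ------------------------------------------------------------------ basics
    @property
    def genotypes(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_genotypes(self) -> int:
        return len(self.calls)

    def sort_map(self) -> None:
        """Stable sort by (chromosome, position, id); ties broken by marker id."""
        m = self.markers
        order = sorted(
            m.index,
            key=lambda mid: (
                chromosome_sort_key(m.at[mid, "chromosome"]),
                m.at[mid, "position_cM"],
                str(mid),
            ),
        )
        self.markers = m.loc[order]
        self.calls = self.calls.loc[:, order]
        self._dosage = None

    def subset_markers(self, ids) -> "MarkerPanel":
        ids = list(ids)
        return MarkerPanel(self.markers.loc[ids].copy(), self.calls[ids].copy())

    def subset_genotypes(self, names) -> "MarkerPanel":
        return MarkerPanel(self.markers.copy(), self.calls.loc[list(names)].copy())

    # ----------------------------------------------------------------- dosages
    def dosage(self) -> pd.DataFrame:
        """Numeric view: PAV 1/0; SNP 1 for the minor allele, 0 for the major.

        Heterozygous IUPAC letters count 0.5 (with a warning); missing stays
        NaN.  The minor allele of a SNP is determined from non-missing calls
        (hets contribute half to each base); frequency ties break to the
        lexicographically smaller base.
        """
        if self._dosage is not None:
            return self._dosage
        out = np.full(self.calls.shape, np.nan)
        het_seen = False
        vals = self.calls.to_numpy(dtype=object)
        for j, mid in enumerate(self.marker_ids):
            col = vals[:, j]
            if self.markers.at[mid, "marker_class"] == "PAV":
                for i, c in enumerate(col):
                    if isinstance(c, str):
                        out[i, j] = float(c)
            else:
                counts: dict[str, float] = {}
                for c in col:
                    if not isinstance(c, str):
                        continue
                    if c in HOMOZYGOUS_BASES:
                        counts[c] = counts.get(c, 0.0) + 1.0
                    elif c in IUPAC_HET:
                        for b in IUPAC_HET[c]:
                            counts[b] = counts.get(b, 0.0) + 0.5
                    else:
                        raise ValueError(f"invalid SNP call {c!r} at {mid}")
                if not counts:
                    continue
                minor = min(counts, key=lambda b: (counts[b], b))
                for i, c in enumerate(col):
                    if not isinstance(c, str):
                        continue
                    if c in HOMOZYGOUS_BASES:
                        out[i, j] = 1.0 if c == minor else 0.0
                    else:
                        het_seen = True
                        out[i, j] = 0.5 if minor in IUPAC_HET[c] else 0.0
        if het_seen:
            warnings.warn(
                "heterozygous IUPAC calls present; counted as dosage 0.5",
                stacklevel=2,
            )
        self._dosage = pd.DataFrame(out, index=self.genotypes, columns=self.marker_ids)
        return self._dosage

    # --------------------------------------------------------------------- IO
    def to_tsv(self, path) -> None:
        """Write the panel in the genotype TSV dialect.

        Header: ``marker_id  chromosome  position_cM  class  <genotype ids...>``;
        one row per marker; missing calls written as ``NA``.
        """
        wide = self.markers.rename(columns={"marker_class": "class"}).copy()
        calls_t = self.calls.T
        calls_t = calls_t.where(calls_t.notna(), MISSING)
        out = pd.concat([wide, calls_t], axis=1)
        out.index.name = "marker_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        markers = pd.DataFrame(
            {
                "chromosome": raw["chromosome"],
                "position_cM": raw["position_cM"].astype(float),
                "marker_class": raw["class"],
            }
        )
        calls = raw.drop(columns=["chromosome", "position_cM", "class"]).T
        calls = calls.replace(MISSING, np.nan)
        _validate_calls(markers, calls)
        return cls(markers, calls)


def _validate_calls(markers: pd.DataFrame, calls: pd.DataFrame) -> None:
    for mid in markers.index:
        cls_ = markers.at[mid, "marker_class"]
        valid = VALID_PAV_CALLS if cls_ == "PAV" else VALID_SNP_CALLS
        col = calls[mid].dropna()
        bad = set(col.unique()) - set(valid)
        if bad:
            raise ValueError(f"invalid {cls_} calls {sorted(bad)} at marker {mid}")


def read_vcf_snps(path, genotypes: list[str] | None = None) -> MarkerPanel:
    """Optional VCF ingest for SNP-class markers (GT field -> IUPAC call).

    Biallelic records only; chromosome names must be ``1A``..``7B`` and the
    POS field is interpreted as cM*1e6 is *not* assumed — a ``cM`` INFO field
    is used when present, else POS is taken as the cM coordinate directly.
    Requires cyvcf2.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = genotypes or list(vcf.samples)
    rows, meta = [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in HOMOZYGOUS_BASES or alt not in HOMOZYGOUS_BASES:
            continue
        pos = rec.INFO.get("cM", rec.POS)
        mid = rec.ID or f"snp_{rec.CHROM}_{rec.POS}"
        het = next(
            (k for k, v in IUPAC_HET.items() if set(v) == {ref, alt}), None
        )
        calls = []
        for g in rec.gt_types:  # 0 hom-ref, 1 het, 2 missing-ish, 3 hom-alt
            if g == 0:
                calls.append(ref)
            elif g == 3:
                calls.append(alt)
            elif g == 1:
                calls.append(het)
            else:
                calls.append(np.nan)
        rows.append(calls)
        meta.append((mid, rec.CHROM, float(pos), "SNP"))
    markers = pd.DataFrame(
        meta, columns=["marker_id", "chromosome", "position_cM", "marker_class"]
    ).set_index("marker_id")
    calls = pd.DataFrame(
        np.array(rows, dtype=object).T, index=samples, columns=markers.index
    )
    return MarkerPanel(markers, calls)
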