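"""Structure-aware single-marker association scan.

The scan follows the PCA + K mixed linear model

    y = X beta + Z u + e,   u ~ N(0, sigma2_u K),   e ~ N(0, sigma2_e I)

with the top genotype principal components as fixed covariates and a
VanRaden-style genomic relationship matrix K as the random-effect
covariance.  Variance components are estimated once per trait/scope by REML
under the no-marker null model and reused for every marker test (the
P3D/EMMAX convention); each marker's dosage coefficient is then tested by
generalized least squares in the eigenspace of K.  An exact per-marker
refit is available behind ``p3d=False`` for small panels.

Marker QC applies, in order: minor-allele frequency, missingness, and
duplicate call vectors (the earlier marker in map order is kept).
Significance uses a suggestive -log10 P threshold plus Benjamini–Hochberg
FDR flags per trait x scope family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .panel import MarkerPanel

log = logging.getLogger(__name__)


# ------------------------------------------------------------------------- QC

@dataclass
class QcReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_removed_duplicate: int
    n_retained: int
    by_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_duplicate": self.n_removed_duplicate,
            "n_retained": self.n_retained,
            "by_class": self.by_class,
        }


def qc_markers(
    panel: MarkerPanel, maf_min: float = 0.05, max_missing: float = 0.30
) -> tuple[MarkerPanel, QcReport]:
    """Filter markers: MAF, then missingness, then exact duplicates.

    Each marker is counted in the first rule that removes it.  MAF is
    computed on non-missing calls; a duplicate has an identical call vector
    (including the missingness pattern) to an earlier-retained marker in map
    order.
    """
    if panel.n_markers == 0:
        raise ValueError("empty panel")
    dose = panel.dosage()
    freq = dose.mean(axis=0, skipna=True)
    maf = np.minimum(freq, 1.0 - freq)
    missing = dose.isna().mean(axis=0)

    removed = {"maf": [], "missing": [], "duplicate": []}
    seen: dict[tuple, str] = {}
    keep = []
    for mid in panel.marker_ids:  # map order
        if not np.isfinite(maf[mid]) or maf[mid] < maf_min:
            removed["maf"].append(mid)
            continue
        if missing[mid] > max_missing:
            removed["missing"].append(mid)
            continue
        key = tuple(
            "NA" if not isinstance(c, str) else c for c in panel.calls[mid]
        )
        if key in seen:
            removed["duplicate"].append(mid)
            continue
        seen[key] = mid
        keep.append(mid)
    if not keep:
        raise ValueError("all markers removed by QC")

    cls = panel.markers["marker_class"]
    by_class = {
        c: {
            "n_input": int((cls == c).sum()),
            "n_retained": int(cls.loc[keep].eq(c).sum()),
        }
        for c in ("PAV", "SNP")
    }
    report = QcReport(
        n_input=panel.n_markers,
        n_removed_maf=len(removed["maf"]),
        n_removed_missing=len(removed["missing"]),
        n_removed_duplicate=len(removed["duplicate"]),
        n_retained=len(keep),
        by_class=by_class,
    )
    return panel.subset_markers(keep), report


# -------------------------------------------------------------------- kinship

def _imputed_dosage(panel: MarkerPanel) -> pd.DataFrame:
    dose = panel.dosage()
    return dose.fillna(dose.mean(axis=0))


def kinship(panel: MarkerPanel) -> pd.DataFrame:
    """VanRaden-style genomic relationship matrix.

    Centered dosage cross-product scaled by sum(2 p (1-p)); missing dosages
    are marker-mean imputed for K only.
    """
    if panel.n_genotypes < 2 or panel.n_markers < 2:
        raise ValueError("kinship needs >=2 genotypes and >=2 markers")
    M = _imputed_dosage(panel)
    p = M.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    Z = (M.loc[:, poly] - p[poly]).to_numpy()
    denom = float((2.0 * p[poly] * (1.0 - p[poly])).sum())
    K = Z @ Z.T / denom
    return pd.DataFrame(K, index=panel.genotypes, columns=panel.genotypes)


def genotype_pcs(panel: MarkerPanel, n_pcs: int = 6) -> pd.DataFrame:
    """Top principal-component scores of the centered dosage matrix.

    Scores are orthogonal (U * singular values); each loading vector's
    largest-magnitude element is positive, the same convention as the trait
    PCA.  If the matrix has lower rank, fewer PCs are returned with a
    warning in the log.
    """
    if n_pcs >= panel.n_genotypes:
        raise ValueError("n_pcs must be smaller than the number of genotypes")
    M = _imputed_dosage(panel)
    Z = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if rank < n_pcs:
        log.warning("dosage rank %d < requested %d PCs", rank, n_pcs)
    n_pcs = min(n_pcs, rank)
    for j in range(n_pcs):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        scores, index=panel.genotypes, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


# ------------------------------------------------------------------- MLM scan

@dataclass
class NullModel:
    h2: float            # sigma2_u / (sigma2_u + sigma2_e) on the K scale
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float


def _reml_null_neg2(h: float, yr: np.ndarray, Xr: np.ndarray, s: np.ndarray) -> float:
    n, p = Xr.shape
    d = h * s + (1.0 - h)
    if np.any(d <= 0):
        return np.inf
    w = 1.0 / d
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    r = yr - Xr @ beta
    quad = float(r @ (w * r))
    if quad <= 0:
        return np.inf
    s2 = quad / (n - p)
    return (n - p) * np.log(s2) + float(np.sum(np.log(d))) + logdet_XtWX


def fit_null_model(
    yr: np.ndarray, Xr: np.ndarray, s: np.ndarray
) -> NullModel:
    """1-D REML over the heritability ratio in the eigenbasis of K."""
    res = optimize.minimize_scalar(
        _reml_null_neg2,
        bounds=(0.0, 1.0 - 1e-6),
        args=(yr, Xr, s),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h = float(res.x)
    # the boundary h = 0 (no genetic variance) is checked explicitly
    if _reml_null_neg2(0.0, yr, Xr, s) <= res.fun:
        h = 0.0
    n, p = Xr.shape
    d = h * s + (1.0 - h)
    w = 1.0 / d
    Xw = Xr * w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    s2 = float(r @ (w * r)) / (n - p)
    neg2 = _reml_null_neg2(h, yr, Xr, s)
    return NullModel(
        h2=h,
        sigma2_u=h * s2,
        sigma2_e=(1.0 - h) * s2,
        reml_loglik=-0.5 * (neg2 + (n - p) * np.log(2 * np.pi)),
    )


def mlm_scan(
    y: pd.Series,
    panel: MarkerPanel,
    pcs: pd.DataFrame | None,
    K: pd.DataFrame | None,
    p3d: bool = True,
) -> pd.DataFrame:
    """Single-marker mixed-model scan of one trait.

    ``y`` is indexed by genotype and must align with the panel; markers
    monomorphic after imputation are skipped with a log entry.  Passing
    ``pcs=None`` and ``K=None`` degrades to a naive unstructured scan (used
    as the confounding baseline).

    Returns one row per tested marker: effect, stat, p, neg_log10_p plus the
    map columns; the fitted null model is attached as ``.attrs["null"]``.
    """
    geno = [g for g in y.index if g in set(panel.genotypes)]
    if len(geno) < len(y):
        log.warning("dropping %d phenotyped genotypes absent from panel",
                    len(y) - len(geno))
    yv = y.loc[geno].to_numpy(dtype=float)
    if np.isnan(yv).any():
        keep = ~np.isnan(yv)
        geno = [g for g, k in zip(geno, keep) if k]
        yv = yv[keep]
    n = len(geno)

    cols = [np.ones(n)]
    if pcs is not None:
        cols.append(pcs.loc[geno].to_numpy(dtype=float))
    X0 = np.column_stack(cols)

    if K is not None:
        Km = K.loc[geno, geno].to_numpy(dtype=float)
        svals, U = np.linalg.eigh(Km)
        svals = np.clip(svals, 0.0, None)
        yr, X0r = U.T @ yv, U.T @ X0
    else:
        svals, U = np.zeros(n), np.eye(n)
        yr, X0r = yv, X0

    null = fit_null_model(yr, X0r, svals) if K is not None else NullModel(
        0.0, 0.0, float(np.var(yv, ddof=X0.shape[1])), np.nan
    )
    d = null.h2 * svals + (1.0 - null.h2)
    w0 = 1.0 / d

    dose = _imputed_dosage(panel).loc[geno]
    rows = []
    for mid in panel.marker_ids:
        g = dose[mid].to_numpy(dtype=float)
        if np.var(g) <= 0:
            log.info("skipping monomorphic marker %s", mid)
            continue
        gr = U.T @ g
        if p3d or K is None:
            w = w0
        else:
            per = fit_null_model(yr, np.column_stack([X0r, gr]), svals)
            w = 1.0 / (per.h2 * svals + (1.0 - per.h2))
        Xf = np.column_stack([X0r, gr])
        sw = np.sqrt(w)
        Xw = Xf * sw[:, None]
        yw = yr * sw
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = yw - Xw @ beta
        dfres = n - Xf.shape[1]
        s2 = float(resid @ resid) / dfres
        se = float(np.sqrt(s2 * np.linalg.inv(XtX)[-1, -1]))
        if se > 0:
            tstat = beta[-1] / se
            p = float(2.0 * stats.t.sf(abs(tstat), dfres))
        else:  # exact fit (noiseless data): report the floor p-value
            tstat = np.inf if beta[-1] >= 0 else -np.inf
            p = 0.0
        rows.append(
            {
                "marker_id": mid,
                "chromosome": panel.markers.at[mid, "chromosome"],
                "position_cM": panel.markers.at[mid, "position_cM"],
                "effect": float(beta[-1]),
                "stat": float(tstat),
                "p": max(p, 5e-324),
                "neg_log10_p": -np.log10(max(p, 5e-324)),
            }
        )
    out = pd.DataFrame(rows).set_index("marker_id")
    out.attrs["null"] = null
    out.attrs["n"] = n
    return out


# -------------------------------------------------------------- FDR and MTAs

def bh_fdr(pvals: pd.Series, q: float = 0.05) -> tuple[pd.Series, float]:
    """Benjamini–Hochberg step-up flags and the realized p cutoff.

    Returns a boolean Series aligned with ``pvals`` and the largest rejected
    p-value (NaN when nothing is rejected).
    """
    if len(pvals) == 0:
        raise ValueError("empty p-value family")
    reject, *_ = multipletests(pvals.to_numpy(), alpha=q, method="fdr_bh")
    flags = pd.Series(reject, index=pvals.index, name="fdr_significant")
    cutoff = float(pvals[flags].max()) if flags.any() else np.nan
    return flags, cutoff


def call_mtas(
    scans: dict[tuple[str, str], pd.DataFrame],
    suggestive: float = 3.0,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Marker-trait associations from per-trait, per-scope scan results.

    ``scans`` maps (trait, scope) — scope is a year label or "across" — to
    the scan frame.  BH-FDR runs within each trait x scope family over the
    full scan; an MTA is any marker at -log10 p >= ``suggestive``, carrying
    its FDR flag.
    """
    rows = []
    for (trait, scope), scan in scans.items():
        if scan.empty:
            continue
        flags, _ = bh_fdr(scan["p"], q=fdr_q)
        hits = scan[scan["neg_log10_p"] >= suggestive]
        for mid, r in hits.iterrows():
            rows.append(
                {
                    "marker_id": mid,
                    "chromosome": r["chromosome"],
                    "position_cM": r["position_cM"],
                    "trait": trait,
                    "scope": str(scope),
                    "p": r["p"],
                    "neg_log10_p": r["neg_log10_p"],
                    "fdr_significant": bool(flags[mid]),
                }
            )
    cols = [
        "marker_id", "chromosome", "position_cM", "trait", "scope",
        "p", "neg_log10_p", "fdr_significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def mta_summary(mtas: pd.DataFrame) -> pd.DataFrame:
    """Per-trait, per-scope MTA counts with FDR counts in parentheses-style
    companion columns, plus row totals (the bookkeeping table layout)."""
    if mtas.empty:
        return pd.DataFrame(columns=["trait"])
    total = mtas.pivot_table(
        index="trait", columns="scope", values="marker_id", aggfunc="count",
        fill_value=0,
    )
    fdr = mtas[mtas["fdr_significant"]].pivot_table(
        index="trait", columns="scope", values="marker_id", aggfunc="count",
        fill_value=0,
    ).reindex(index=total.index, columns=total.columns, fill_value=0)
    out = pd.concat({"n": total, "n_fdr": fdr}, axis=1)
    out[("n", "Total")] = total.sum(axis=1)
    out[("n_fdr", "Total")] = fdr.sum(axis=1)
    return out
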