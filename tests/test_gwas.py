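"""Marker QC, kinship, genotype PCs, the P3D mixed-model scan, and BH-FDR,
each against an independent oracle or closed-form limit."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import durumpanel as dp
from durumpanel.panel import MarkerPanel


def _pav_panel(call_rows, positions=None, chrom="1A"):
    """Panel from a list of per-genotype PAV call strings ('0'/'1'/None)."""
    n, m = len(call_rows), len(call_rows[0])
    ids = [f"M{j}" for j in range(m)]
    markers = pd.DataFrame(
        {
            "chromosome": [chrom] * m,
            "position_cM": positions or list(np.linspace(0, 50, m)),
            "marker_class": ["PAV"] * m,
        },
        index=pd.Index(ids, name="marker_id"),
    )
    calls = pd.DataFrame(
        [[c if c is not None else np.nan for c in row] for row in call_rows],
        index=[f"G{i}" for i in range(n)], columns=ids,
    )
    return MarkerPanel(markers, calls)


# -------------------------------------------------------------------------- QC

def test_qc_rules_apply_in_order_and_reconcile():
    rows = []
    for i in range(100):
        rows.append(
            [
                "1" if i < 4 else "0",            # M0: maf 0.04 -> removed
                None if i < 31 else "1" if i % 2 else "0",  # M1: 31% missing
                "1" if i % 2 else "0",            # M2: kept
                "1" if i % 2 else "0",            # M3: duplicate of M2
                "0" if i % 2 else "1",            # M4: complement, kept
            ]
        )
    panel = _pav_panel(rows)
    out, rep = dp.qc_markers(panel)
    assert list(out.marker_ids) == ["M2", "M4"]
    assert rep.n_removed_maf == 1
    assert rep.n_removed_missing == 1
    assert rep.n_removed_duplicate == 1
    assert rep.n_input == rep.n_retained + rep.n_removed_maf \
        + rep.n_removed_missing + rep.n_removed_duplicate
    assert rep.by_class["PAV"]["n_retained"] == rep.n_retained


def test_qc_all_removed_errors():
    panel = _pav_panel([["1", "1"]] * 50)  # monomorphic -> maf 0
    with pytest.raises(ValueError, match="all markers removed"):
        dp.qc_markers(panel)


# --------------------------------------------------------------------- kinship

def test_kinship_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    rows = [
        ["1" if rng.random() < 0.5 else "0" for _ in range(10)] for _ in range(5)
    ]
    rows[1][3] = None  # exercise mean imputation
    panel = _pav_panel(rows)
    K = dp.kinship(panel)
    dose = panel.dosage()
    M = dose.fillna(dose.mean()).to_numpy()
    p = M.mean(axis=0)
    poly = (p > 0) & (p < 1)
    denom = float((2 * p[poly] * (1 - p[poly])).sum())
    expect = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            expect[i, j] = sum(
                (M[i, k] - p[k]) * (M[j, k] - p[k]) for k in np.where(poly)[0]
            ) / denom
    assert np.allclose(K.to_numpy(), expect, atol=1e-12)


def test_kinship_identity_by_state_and_psd(small_panel_sim):
    sub = small_panel_sim.panel.subset_genotypes(
        small_panel_sim.panel.genotypes[:40]
    )
    twin = sub.calls.iloc[0].copy()
    calls = pd.concat([sub.calls, twin.to_frame("G_twin").T])
    panel = MarkerPanel(sub.markers.copy(), calls)
    K = dp.kinship(panel)
    g0 = panel.genotypes[0]
    assert K.at[g0, "G_twin"] == pytest.approx(K.at[g0, g0], abs=1e-12)
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K.to_numpy()).min() >= -1e-8


# ------------------------------------------------------------------------- PCs

def test_pcs_separate_diverged_subpops_orthogonal_and_permutation_stable():
    cfg = dp.PanelConfig(
        n_genotypes=120, n_landraces=60, n_subpops=2, n_markers=400,
        fst_like_differentiation=0.35, admixture_concentration=40.0,
        missing_rate=0.0, seed=3,
    )
    sim = dp.simulate_panel(cfg)
    pcs = dp.genotype_pcs(sim.panel, 4)
    grp = sim.home_subpop.to_numpy()
    r = np.corrcoef(pcs["PC1"], grp)[0, 1]
    assert abs(r) > 0.9
    gram = pcs.to_numpy().T @ pcs.to_numpy()
    assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-6)
    # marker-order permutation: scores identical up to sign
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(sim.panel.marker_ids))
    shuffled = MarkerPanel(sim.panel.markers.loc[perm], sim.panel.calls[perm])
    pcs2 = dp.genotype_pcs(shuffled, 4)
    for c in pcs.columns:
        assert (
            np.allclose(pcs[c], pcs2[c], atol=1e-6)
            or np.allclose(pcs[c], -pcs2[c], atol=1e-6)
        )


# -------------------------------------------------------------------- MLM scan

def test_mlm_reduces_to_ols_without_genetic_variance(structured_panel_300):
    sim = structured_panel_300
    pq, _ = dp.qc_markers(sim.panel)
    pq = pq.subset_markers(pq.marker_ids[:40])
    K = dp.kinship(sim.panel)
    pcs = dp.genotype_pcs(sim.panel, 6)
    rng = np.random.default_rng(2)
    y = pd.Series(rng.normal(size=pq.n_genotypes), index=pq.genotypes)
    scan = dp.mlm_scan(y, pq, pcs, K)
    # precondition of the limit: the null REML detects no genetic variance
    # (with iid phenotypes the profile in h2 is nearly flat, so not every
    # draw ends on the boundary; this one does)
    assert scan.attrs["null"].h2 == 0.0
    dose = pq.dosage()
    dose = dose.fillna(dose.mean())
    for mid in pq.marker_ids[:10]:
        X = sm.add_constant(
            np.column_stack([pcs.to_numpy(), dose[mid].to_numpy()])
        )
        ols_p = sm.OLS(y.to_numpy(), X).fit().pvalues[-1]
        assert scan.at[mid, "p"] == pytest.approx(ols_p, abs=1e-6)


def test_mlm_pvalues_invariant_to_genotype_order(small_panel_sim):
    sim = small_panel_sim
    pq, _ = dp.qc_markers(sim.panel)
    pq = pq.subset_markers(pq.marker_ids[:60])
    K = dp.kinship(pq)
    pcs = dp.genotype_pcs(pq, 6)
    rng = np.random.default_rng(4)
    y = pd.Series(
        sim.q.to_numpy() @ np.array([2.0, -1.0, 0.5, 1.5, -0.5])
        + rng.normal(0, 1, pq.n_genotypes),
        index=pq.genotypes,
    )
    scan1 = dp.mlm_scan(y, pq, pcs, K)
    order = list(rng.permutation(pq.genotypes))
    panel2 = pq.subset_genotypes(order)
    scan2 = dp.mlm_scan(y.loc[order], panel2, pcs.loc[order], K.loc[order, order])
    assert np.allclose(scan1["p"], scan2["p"], rtol=1e-6)


def test_monomorphic_marker_skipped():
    rows = [["1", "1" if i % 2 else "0"] for i in range(20)]
    panel = _pav_panel(rows)
    y = pd.Series(np.arange(20.0), index=panel.genotypes)
    scan = dp.mlm_scan(y, panel, None, None)
    assert list(scan.index) == ["M1"]


# ------------------------------------------------------------------------- FDR

def test_bh_trivial_families():
    ones = pd.Series(np.ones(8))
    flags, cutoff = dp.bh_fdr(ones)
    assert not flags.any() and np.isnan(cutoff)
    small = pd.Series([0.001] * 10)
    flags, cutoff = dp.bh_fdr(small)
    assert flags.all() and cutoff == pytest.approx(0.001)


def _bh_enumerate(pvals, q):
    """Exhaustive step-up: largest k with p_(k) <= k/m * q; reject smallest k."""
    m = len(pvals)
    order = np.argsort(pvals)
    ks = [k for k in range(1, m + 1) if pvals[order[k - 1]] <= k / m * q]
    k_star = max(ks) if ks else 0
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


def test_bh_matches_exhaustive_enumeration():
    p = np.round(np.arange(0.01, 0.105, 0.01), 3)
    flags, _ = dp.bh_fdr(pd.Series(p))
    assert np.array_equal(flags.to_numpy(), _bh_enumerate(p, 0.05))
    rng = np.random.default_rng(7)
    for _ in range(25):
        p = rng.uniform(0, 0.4, size=rng.integers(1, 11))
        flags, _ = dp.bh_fdr(pd.Series(p))
        assert np.array_equal(flags.to_numpy(), _bh_enumerate(p, 0.05))


def test_bh_monotone_in_q():
    rng = np.random.default_rng(8)
    p = pd.Series(rng.uniform(0, 1, 200) ** 2)
    prev = None
    for q in (0.01, 0.05, 0.10, 0.25):
        flags, _ = dp.bh_fdr(p, q=q)
        if prev is not None:
            assert (prev <= flags).all()   # rejections grow with q
        prev = flags


# ------------------------------------------------------------------------ MTAs

def test_call_mtas_threshold_and_bookkeeping():
    rng = np.random.default_rng(9)
    idx = [f"M{i}" for i in range(50)]

    def scan_with(max_neglog):
        p = rng.uniform(0.05, 1.0, 50)
        p[0] = 10 ** (-max_neglog)
        return pd.DataFrame(
            {
                "chromosome": "2A",
                "position_cM": np.linspace(0, 50, 50),
                "p": p,
                "neg_log10_p": -np.log10(p),
            },
            index=pd.Index(idx, name="marker_id"),
        )

    none = dp.call_mtas({("Yield", "2013"): scan_with(2.9)})
    assert none.empty
    scans = {
        ("Yield", "2013"): scan_with(6.0),
        ("Yield", "2014"): scan_with(4.0),
        ("W", "2013"): scan_with(5.0),
    }
    mtas = dp.call_mtas(scans)
    summary = dp.mta_summary(mtas)
    assert summary[("n", "Total")].sum() == len(mtas)
    assert int(summary[("n_fdr", "Total")].sum()) == int(mtas["fdr_significant"].sum())
    assert (summary["n_fdr"].to_numpy() <= summary["n"].to_numpy()).all()
    assert (mtas["neg_log10_p"] >= 3.0).all()
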