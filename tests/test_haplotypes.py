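"""Per-subpopulation major-allele calls and haplotype-block segmentation."""

import numpy as np
import pandas as pd
import pytest

import durumpanel as dp
from durumpanel.haplotypes import HaplotypeBlock, allele_matrix
from durumpanel.hotspots import Hotspot
from durumpanel.panel import MarkerPanel

from conftest import make_mtas


def _panel_from_sp_patterns(patterns, n_per_sp=6, positions=None, chrom="2A"):
    """PAV panel: ``patterns[sp]`` is the call string per marker for that SP
    (every member of the SP carries it)."""
    sps = sorted(patterns)
    m = len(next(iter(patterns.values())))
    ids = [f"M{j}" for j in range(m)]
    markers = pd.DataFrame(
        {
            "chromosome": [chrom] * m,
            "position_cM": positions or [float(j) * 0.5 for j in range(m)],
            "marker_class": ["PAV"] * m,
        },
        index=pd.Index(ids, name="marker_id"),
    )
    rows, names, labels = [], [], []
    for sp in sps:
        for i in range(n_per_sp):
            names.append(f"{sp}_g{i}")
            labels.append(sp)
            rows.append(list(patterns[sp]))
    calls = pd.DataFrame(rows, index=names, columns=ids)
    panel = MarkerPanel(markers, calls)
    subpops = pd.Series(labels, index=names, name="subpop")
    hotspot = Hotspot(
        id="2A.1", chromosome=chrom, start_cM=0.0,
        end_cM=markers["position_cM"].max(),
        members=make_mtas([]), years=("2013", "2014"), traits=("W",),
        n_fdr_significant=0,
    )
    return panel, subpops, hotspot


def test_major_allele_frequency_and_na_rules():
    patterns = {f"SP{k}": "1" for k in range(1, 6)}
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns, n_per_sp=8)
    # SP1: 6/8 carry '1' -> freq 0.75 called; SP2: 4/8 -> 0.5 tie -> NA;
    # SP3: 5/8 = 0.625 called
    calls = panel.calls.copy()
    calls.loc[[f"SP1_g{i}" for i in (0, 1)], "M0"] = "0"
    calls.loc[[f"SP2_g{i}" for i in range(4)], "M0"] = "0"
    calls.loc[[f"SP3_g{i}" for i in range(3)], "M0"] = "0"
    panel = MarkerPanel(panel.markers, calls)
    got = dp.sp_allele_calls(panel, subpops, hotspot).set_index("subpop")
    assert got.at["SP1", "freq"] == pytest.approx(0.75)
    assert got.at["SP1", "allele"] == "1" and got.at["SP1", "called"]
    assert got.at["SP2", "freq"] == pytest.approx(0.5)
    assert got.at["SP2", "allele"] == "NA" and not got.at["SP2", "called"]
    assert got.at["SP3", "allele"] == "1"   # 0.625 >= 0.60 -> called


def test_sub_threshold_frequency_is_na():
    patterns = {f"SP{k}": "11" for k in range(1, 6)}
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns, n_per_sp=20)
    calls = panel.calls.copy()
    calls.loc[[f"SP1_g{i}" for i in range(9)], "M0"] = "0"  # freq 0.55
    panel = MarkerPanel(panel.markers, calls)
    got = dp.sp_allele_calls(panel, subpops, hotspot)
    sp1_m0 = got[(got["subpop"] == "SP1") & (got["marker_id"] == "M0")].iloc[0]
    assert sp1_m0["freq"] == pytest.approx(0.55)
    assert sp1_m0["allele"] == "NA"


def test_private_run_yields_single_block_with_correct_set():
    patterns = {
        "SP1": "11111", "SP2": "11111", "SP4": "11111", "SP5": "11111",
        "SP3": "10001",  # SP3 private alleles at markers 1..3
    }
    patterns["SP3"] = "1" + "000" + "1"
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns)
    calls = dp.sp_allele_calls(panel, subpops, hotspot)
    hbs = dp.define_hbs(calls, hotspot)
    assert len(hbs) == 1
    hb = hbs[0]
    assert hb.id == "2A.1.HB1"
    assert hb.marker_ids == ("M1", "M2", "M3")
    assert hb.diff_subpops == frozenset({"SP3"})
    assert hb.mean_freq["SP3"] == pytest.approx(1.0)
    assert hb.haplotypes["SP3"] == "0/0/0"
    assert hb.haplotypes["SP1"] == "1/1/1"


def test_no_differentiation_no_blocks():
    patterns = {f"SP{k}": "1111" for k in range(1, 6)}
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns)
    hbs = dp.define_hbs(dp.sp_allele_calls(panel, subpops, hotspot), hotspot)
    assert hbs == []


def _brute_force_runs(diff_sets):
    """Independent segmentation oracle: maximal same-set runs over markers."""
    runs, cur, cur_set = [], [], frozenset()
    for mid, s in diff_sets:
        if not s:
            if cur:
                runs.append((tuple(cur), cur_set))
            cur, cur_set = [], frozenset()
        elif cur and s == cur_set:
            cur.append(mid)
        else:
            if cur:
                runs.append((tuple(cur), cur_set))
            cur, cur_set = [mid], s
    if cur:
        runs.append((tuple(cur), cur_set))
    return runs


def test_two_runs_split_by_nondifferentiating_marker():
    # SP3 private at markers 0-1 and 3-4; marker 2 shared by everyone
    patterns = {f"SP{k}": "11111" for k in (1, 2, 4, 5)}
    patterns["SP3"] = "00100"
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns)
    calls = dp.sp_allele_calls(panel, subpops, hotspot)
    hbs = dp.define_hbs(calls, hotspot)
    expected = _brute_force_runs(
        [
            ("M0", frozenset({"SP3"})), ("M1", frozenset({"SP3"})),
            ("M2", frozenset()),
            ("M3", frozenset({"SP3"})), ("M4", frozenset({"SP3"})),
        ]
    )
    assert [hb.marker_ids for hb in hbs] == [run for run, _ in expected]
    assert [hb.id for hb in hbs] == ["2A.1.HB1", "2A.1.HB2"]


def test_raising_threshold_never_adds_differentiating_markers():
    # one-subpopulation-private variation (the pattern the rule targets):
    # under it a stricter calling threshold can only erode blocks
    rng = np.random.default_rng(0)
    base = rng.choice(["0", "1"], size=12)
    patterns = {f"SP{k}": "".join(base) for k in range(1, 6)}
    private = base.copy()
    flip_at = rng.random(12) < 0.5
    private[flip_at] = np.where(private[flip_at] == "1", "0", "1")
    patterns["SP3"] = "".join(private)
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns, n_per_sp=12)
    calls_df = panel.calls.copy()
    flip = rng.random(calls_df.shape) < 0.15   # within-SP noise
    flipped = calls_df.to_numpy(dtype=object)
    flipped[flip] = np.where(flipped[flip] == "1", "0", "1")
    panel = MarkerPanel(panel.markers, pd.DataFrame(
        flipped, index=calls_df.index, columns=calls_df.columns
    ))
    sp_calls = dp.sp_allele_calls(panel, subpops, hotspot)
    prev = None
    for thr in (0.55, 0.60, 0.70, 0.85, 0.95):
        hbs = dp.define_hbs(sp_calls, hotspot, diff_threshold=thr)
        n_diff = sum(len(hb.marker_ids) for hb in hbs)
        if prev is not None:
            assert n_diff <= prev
        prev = n_diff


def test_trait_links_direct_and_indirect():
    patterns = {f"SP{k}": "11111" for k in (1, 2, 4, 5)}
    patterns["SP3"] = "00011"   # SP3 private at markers 0-2
    patterns["SP2"] = "11100"   # SP2 private at markers 3-4
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns)
    calls = dp.sp_allele_calls(panel, subpops, hotspot)
    hbs = dp.define_hbs(calls, hotspot)
    assert [hb.diff_subpops for hb in hbs] == [
        frozenset({"SP3"}), frozenset({"SP2"})
    ]
    mtas = make_mtas([("M0", "2A", 0.0, "W", 2013)])
    links = dp.link_hb_traits(hbs, mtas, [hotspot])
    by_hb = links.groupby("hb_id")
    assert by_hb.get_group(hbs[0].id)["direct"].all()
    assert set(by_hb.get_group(hbs[0].id)["trait"]) == {"W"}
    # later blocks carry no marker-level MTA -> inherit hotspot traits
    assert not by_hb.get_group(hbs[1].id)["direct"].any()
    assert set(by_hb.get_group(hbs[1].id)["trait"]) == set(hotspot.traits)


def test_allele_matrix_layout():
    patterns = {f"SP{k}": "101" for k in range(1, 6)}
    panel, subpops, hotspot = _panel_from_sp_patterns(patterns)
    mat = allele_matrix(dp.sp_allele_calls(panel, subpops, hotspot))
    assert list(mat.index) == ["M0", "M1", "M2"]
    assert mat.loc["M0", "SP1"] == "1" and mat.loc["M1", "SP3"] == "0"
    assert mat.loc["M0", "SP2_freq"] == 1.0


def test_planted_private_run_recovered_through_generator():
    """End of the chain on generator output: a fully fixed SP-private run is
    recovered exactly, with the right differentiating subpopulation."""
    run = dp.SpPrivateRun(subpop=2, chromosome="2A", start_cM=40.0, n_markers=4)
    cfg = dp.PanelConfig(
        n_genotypes=150, n_landraces=90, n_markers=300, missing_rate=0.0,
        admixture_concentration=60.0,  # essentially pure lines
        fst_like_differentiation=0.02, private_runs=[run], seed=33,
    )
    sim = dp.simulate_panel(cfg)
    subpops = dp.assign_subpops(sim.q)
    planted = list(
        sim.subpop_freqs.index[
            (sim.subpop_freqs["SP3"] == 0.0)
            & (sim.subpop_freqs.drop(columns="SP3") == 1.0).all(axis=1)
        ]
    )
    assert len(planted) == 4
    pos = sim.panel.markers.loc[planted, "position_cM"]
    hotspot = Hotspot(
        id="2A.1", chromosome="2A", start_cM=float(pos.min()) - 0.5,
        end_cM=float(pos.max()) + 0.5, members=make_mtas([]),
        years=("2013", "2014"), traits=("Yield",), n_fdr_significant=0,
    )
    calls = dp.sp_allele_calls(sim.panel, subpops, hotspot)
    hbs = dp.define_hbs(calls, hotspot)
    rec = [hb for hb in hbs if set(planted) <= set(hb.marker_ids)]
    assert rec and rec[0].diff_subpops == frozenset({"SP3"})
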