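"""Structure analyses: membership thresholding, structure regression,
partitioned ANOVA with Tukey–Kramer letters, PCA, Ward clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

import durumpanel as dp
from durumpanel.structure import ADMIXED, PcaResult, flat_clusters, linkage_to_newick


def _q(rows, cols=5):
    return pd.DataFrame(
        rows, columns=[f"SP{i+1}" for i in range(cols)],
        index=[f"G{i}" for i in range(len(rows))],
    )


# ------------------------------------------------------------------ membership

def test_assignment_threshold_is_strict():
    q = _q(
        [
            [0.9, 0.05, 0.03, 0.01, 0.01],
            [0.79, 0.21, 0.0, 0.0, 0.0],
            [0.80, 0.20, 0.0, 0.0, 0.0],   # exactly at threshold -> admixed
        ]
    )
    got = dp.assign_subpops(q)
    assert list(got) == ["SP1", ADMIXED, ADMIXED]


def test_assignment_validates_row_sums():
    with pytest.raises(ValueError, match="sum"):
        dp.assign_subpops(_q([[0.5, 0.1, 0.1, 0.1, 0.1]]))


# ------------------------------------------------------------------ regression

def test_structure_regression_exact_linear_and_oracle():
    rng = np.random.default_rng(0)
    q = rng.dirichlet(np.ones(5) * 0.5, size=40)
    qdf = _q(list(q))
    exact = pd.DataFrame(
        {"t": q @ np.array([3.0, 1.0, -2.0, 0.5, 0.0])}, index=qdf.index
    )
    assert dp.structure_regression(exact, qdf)["t"] == pytest.approx(1.0, abs=1e-9)

    # 10-genotype fixture vs normal-equations oracle
    q10 = _q(list(rng.dirichlet(np.ones(5) * 0.5, size=10)))
    y = pd.DataFrame({"t": rng.normal(size=10)}, index=q10.index)
    got = dp.structure_regression(y, q10)["t"]
    X = np.column_stack([np.ones(10), q10.to_numpy()[:, :-1]])
    beta = np.linalg.solve(X.T @ X, X.T @ y["t"].to_numpy())
    sse = float(((y["t"].to_numpy() - X @ beta) ** 2).sum())
    sst = float(((y["t"] - y["t"].mean()) ** 2).sum())
    assert got == pytest.approx(1 - sse / sst, abs=1e-10)
    # invariance to which (redundant) q column is dropped
    perm = qdf[["SP3", "SP1", "SP2", "SP5", "SP4"]]
    assert dp.structure_regression(exact, perm)["t"] == pytest.approx(1.0, abs=1e-9)


def test_structure_regression_null_is_small():
    rng = np.random.default_rng(1)
    q = _q(list(rng.dirichlet(np.ones(5), size=1000)))
    y = pd.DataFrame({"t": rng.normal(size=1000)}, index=q.index)
    assert dp.structure_regression(y, q)["t"] <= 0.02


def test_structure_regression_constant_trait_warns_zero():
    q = _q(list(np.full((10, 5), 0.2)))
    y = pd.DataFrame({"t": np.ones(10)}, index=q.index)
    with pytest.warns(UserWarning, match="constant"):
        assert dp.structure_regression(y, q)["t"] == 0.0


# ----------------------------------------------------------------------- ANOVA

def test_partitioned_anova_sums_of_squares_brute_force():
    values = pd.Series(
        [1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 20.0, 22.0, 24.0],
        index=[f"G{i}" for i in range(9)],
    )
    groups = pd.Series(
        ["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=values.index
    )
    cmp_ = dp.partitioned_anova(values, groups)
    grand = values.mean()
    ss_b = sum(
        3 * (values[groups == g].mean() - grand) ** 2 for g in "abc"
    )
    ss_w = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
        for g in "abc"
    )
    assert cmp_.ms_between * cmp_.df_between == pytest.approx(ss_b, abs=1e-9)
    assert cmp_.ms_within * cmp_.df_within == pytest.approx(ss_w, abs=1e-9)
    # partition identity: between + within = total genotype SS
    ss_tot = ((values - grand) ** 2).sum()
    assert ss_b + ss_w == pytest.approx(ss_tot, abs=1e-9)


def test_partitioned_anova_degenerate_and_singleton():
    values = pd.Series([1.0] * 6, index=[f"G{i}" for i in range(6)])
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=values.index)
    assert dp.partitioned_anova(values, groups).f_value == 0.0
    vals = pd.Series([1.0, 2.0, 3.0, 4.0, 9.0], index=[f"G{i}" for i in range(5)])
    grp = pd.Series(["a", "a", "b", "b", "c"], index=vals.index)
    with pytest.warns(UserWarning, match="single-genotype"):
        got = dp.partitioned_anova(vals, grp)
    assert set(got.table["group"]) == {"a", "b"}


def test_partitioned_anova_type_one_error_rate():
    rng = np.random.default_rng(5)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        vals = pd.Series(rng.normal(size=40), index=[f"G{i}" for i in range(40)])
        grp = pd.Series(["a"] * 20 + ["b"] * 20, index=vals.index)
        rejections += dp.partitioned_anova(vals, grp).p_value < 0.05
    rate = rejections / n_rep
    assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_rep)


def test_tukey_letters_agree_with_pairwise_decisions():
    from scipy import stats as sps

    rng = np.random.default_rng(9)
    for _ in range(10):
        means_true = rng.normal(0, 1.5, 5)
        vals, grp = [], []
        for gi, m in enumerate(means_true):
            n_g = rng.integers(4, 9)
            vals.extend(m + rng.normal(0, 1, n_g))
            grp.extend([f"g{gi}"] * n_g)
        values = pd.Series(vals, index=[f"G{i}" for i in range(len(vals))])
        groups = pd.Series(grp, index=values.index)
        cmp_ = dp.partitioned_anova(values, groups)
        tab = cmp_.table.set_index("group")
        qcrit = sps.studentized_range.ppf(0.95, len(tab), cmp_.df_within)
        for a, b in itertools.combinations(tab.index, 2):
            se = np.sqrt(
                cmp_.ms_within / 2 * (1 / tab.at[a, "n"] + 1 / tab.at[b, "n"])
            )
            sig = abs(tab.at[a, "mean"] - tab.at[b, "mean"]) / se > qcrit
            share = bool(set(tab.at[a, "letters"]) & set(tab.at[b, "letters"]))
            assert share != sig


# ------------------------------------------------------------------------- PCA

def test_pca_eigenvalues_match_characteristic_polynomial_oracle():
    corr = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, -0.1], [0.2, -0.1, 1.0]])
    rng = np.random.default_rng(2)
    X = rng.multivariate_normal(np.zeros(3), corr, size=20000)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    res = dp.trait_pca(df)
    sample_corr = df.corr().to_numpy()
    # characteristic polynomial of the 3x3 sample correlation matrix
    c2 = -np.trace(sample_corr)
    c1 = 0.5 * (np.trace(sample_corr) ** 2 - np.trace(sample_corr @ sample_corr))
    c0 = -np.linalg.det(sample_corr)
    roots = sorted(np.roots([1.0, c2, c1, c0]).real, reverse=True)
    got = res.explained.to_numpy() * 3.0
    assert np.allclose(got, roots, atol=1e-8)
    assert res.explained.sum() == pytest.approx(1.0)
    # sign convention: largest-magnitude loading of each component positive
    for c in res.loadings.columns:
        v = res.loadings[c]
        assert v.iloc[int(np.argmax(np.abs(v.to_numpy())))] > 0


def test_pca_isotropic_and_duplicated_trait():
    rng = np.random.default_rng(3)
    iso = pd.DataFrame(rng.normal(size=(5000, 4)), columns=list("abcd"))
    res = dp.trait_pca(iso)
    assert np.all(np.abs(res.explained.to_numpy() - 0.25) < 0.05)
    two = pd.DataFrame({"a": rng.normal(size=500)})
    two["b"] = two["a"] * 2.0 + 1.0
    res2 = dp.trait_pca(two)
    assert res2.explained["PC1"] == pytest.approx(1.0, abs=1e-9)


def test_pca_reconstructs_standardized_matrix():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
    res = dp.trait_pca(df)
    Xs = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
    rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(rec, Xs, atol=1e-8)


# ------------------------------------------------------------------ clustering

def test_ward_recovers_two_separated_groups():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, size=(25, 3))
    b = rng.normal(5, 1, size=(25, 3))
    df = pd.DataFrame(
        np.vstack([a, b]), index=[f"G{i}" for i in range(50)], columns=list("xyz")
    )
    link = dp.ward_cluster(df)
    labels = flat_clusters(link, df.index, 2)
    assert labels.iloc[:25].nunique() == 1 and labels.iloc[25:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[-1]
    nwk = linkage_to_newick(link, list(df.index))
    assert nwk.endswith(";") and "G0:" in nwk


def test_duplicated_row_keeps_partition():
    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, size=(10, 3))
    b = rng.normal(6, 1, size=(10, 3))
    base = np.vstack([a, b])
    df = pd.DataFrame(base, columns=list("xyz"))
    dup = pd.DataFrame(np.vstack([base, base[:1]]), columns=list("xyz"))
    l1 = flat_clusters(dp.ward_cluster(df), df.index, 2)
    l2 = flat_clusters(dp.ward_cluster(dup), dup.index, 2)
    # same bipartition of the original rows; the copy joins its twin's side
    same1 = l1.iloc[:10].nunique() == 1 and l1.iloc[10:20].nunique() == 1
    same2 = l2.iloc[:10].nunique() == 1 and l2.iloc[10:20].nunique() == 1
    assert same1 and same2
    assert l2.iloc[20] == l2.iloc[0]


def test_pearson_matrix_diagonal_and_errors():
    rng = np.random.default_rng(10)
    df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    corr = dp.pearson_matrix(df)
    assert np.allclose(np.diag(corr), 1.0)
    with pytest.raises(ValueError):
        dp.ward_cluster(df.iloc[:1])
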