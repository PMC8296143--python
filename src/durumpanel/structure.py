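"""Trait variation versus genetic population structure.

Membership coefficients ``q`` (admixture proportions over the genetic
subpopulations) are an upstream input; this module assigns genotypes to a
subpopulation when max(q) exceeds a strict threshold (default 0.80, others
are "admixed"), regresses traits on the structure coefficients, compares
germplasm groups with a partitioned ANOVA whose error term is the genotypic
variance retained within groups (Tukey–Kramer letters at P < 0.05), and
summarizes trait covariation with correlation-matrix PCA, Ward clustering
and Pearson correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy

ADMIXED = "admixed"


# ------------------------------------------------------------------ membership

def assign_subpops(q: pd.DataFrame, threshold: float = 0.80) -> pd.Series:
    """Subpopulation label per genotype; strict ``max(q) > threshold``.

    A genotype at exactly the threshold stays admixed.  Rows must sum to 1
    within 1e-6.
    """
    sums = q.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if not bad.empty:
        raise ValueError(f"q rows do not sum to 1: {list(bad.index[:5])}")
    best = q.idxmax(axis=1)
    assigned = best.where(q.max(axis=1) > threshold, ADMIXED)
    return assigned.rename("subpop")


# ------------------------------------------------------------------ regression

def structure_regression(traits: pd.DataFrame, q: pd.DataFrame) -> pd.Series:
    """R-squared of each trait on the membership coefficients.

    One q column is dropped before fitting (rows sum to one, so the design
    would otherwise be collinear with the intercept); R-squared is invariant
    to which column is dropped.
    """
    common = traits.index.intersection(q.index)
    if len(common) < q.shape[1] + 2:
        raise ValueError("need at least k+2 genotypes for the structure regression")
    Xq = sm.add_constant(q.loc[common].iloc[:, :-1].to_numpy())
    out = {}
    for trait in traits.columns:
        yv = traits.loc[common, trait]
        ok = yv.notna()
        if yv[ok].nunique() <= 1:
            warnings.warn(f"constant trait {trait!r}; R^2 set to 0", stacklevel=2)
            out[trait] = 0.0
            continue
        res = sm.OLS(yv[ok].to_numpy(), Xq[ok.to_numpy()]).fit()
        out[trait] = float(res.rsquared)
    return pd.Series(out, name="r_squared")


# ------------------------------------------------------------------ ANOVA

@dataclass
class GroupComparison:
    trait: str
    table: pd.DataFrame       # group, n, mean, se, letters
    f_value: float
    p_value: float
    ms_between: float
    ms_within: float
    df_between: int
    df_within: int


@lru_cache(maxsize=256)
def _studentized_range_crit(conf: float, k: int, df: int) -> float:
    # ppf of the studentized range is expensive; (k, df) repeat across traits
    return float(stats.studentized_range.ppf(conf, k, df))


def _tukey_letters(
    means: pd.Series, ns: pd.Series, ms_error: float, df_error: int, alpha: float
) -> pd.Series:
    """Compact letter display from Tukey–Kramer pairwise decisions.

    Letters come from the maximal sets of mutually non-different groups
    (exhaustive over subsets; group counts here are small), so the display
    can never contradict a pairwise decision.
    """
    groups = list(means.index)
    k = len(groups)
    qcrit = _studentized_range_crit(1 - alpha, k, df_error)
    differ = {}
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt(ms_error / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        stat = abs(means[a] - means[b]) / se if se > 0 else np.inf
        differ[(a, b)] = differ[(b, a)] = stat > qcrit
    maximal = []
    for r in range(k, 0, -1):
        for sub in itertools.combinations(groups, r):
            if any(differ[(a, b)] for a, b in itertools.combinations(sub, 2)):
                continue
            if any(set(sub) <= set(mx) for mx in maximal):
                continue
            maximal.append(sub)
    maximal.sort(key=lambda sub: -max(means[g] for g in sub))
    letters = {g: "" for g in groups}
    for letter, sub in zip("abcdefghijklmnopqrstuvwxyz", maximal):
        for g in sub:
            letters[g] += letter
    return pd.Series(letters)


def partitioned_anova(
    values: pd.Series,
    grouping: pd.Series,
    trait: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Group comparison with the within-group genotypic variance as error.

    ``values`` holds one (BLUP or mean) value per genotype; ``grouping`` maps
    genotype to germplasm group.  The genotype sum of squares is partitioned
    into between-group and within-group parts and F = MS(between) /
    MS(genotypes within groups).  Groups with fewer than two genotypes are
    excluded with a warning.
    """
    df = pd.DataFrame({"value": values, "group": grouping}).dropna()
    sizes = df.groupby("group")["value"].count()
    small = sizes[sizes < 2]
    if not small.empty:
        warnings.warn(
            f"excluding single-genotype groups: {list(small.index)}", stacklevel=2
        )
        df = df[~df["group"].isin(small.index)]
    sizes = df.groupby("group")["value"].count()
    if len(sizes) < 2:
        raise ValueError("need at least two groups with >=2 genotypes")

    grand = df["value"].mean()
    means = df.groupby("group")["value"].mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(
        sum(
            ((g["value"] - g["value"].mean()) ** 2).sum()
            for _, g in df.groupby("group")
        )
    )
    df_b = len(sizes) - 1
    df_w = len(df) - len(sizes)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w if df_w > 0 else np.nan
    f_val = ms_b / ms_w if ms_w > 0 else 0.0
    if ss_between == 0.0:
        f_val = 0.0
    p_val = float(stats.f.sf(f_val, df_b, df_w)) if ms_w > 0 else np.nan

    letters = _tukey_letters(means, sizes, ms_w, df_w, alpha)
    se = np.sqrt(ms_w / sizes)
    table = pd.DataFrame(
        {"n": sizes, "mean": means, "se": se, "letters": letters}
    ).reset_index(names="group")
    return GroupComparison(trait, table, f_val, p_val, ms_b, ms_w, df_b, df_w)


# ------------------------------------------------------------------ PCA

@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame       # traits x components
    explained: pd.Series         # fractions, sum to 1


def trait_pca(traits: pd.DataFrame) -> PcaResult:
    """Eigen-decomposition of the trait correlation matrix.

    Constant traits are dropped with a warning.  Sign convention: the
    largest-magnitude element of every loading vector is positive.  Scores
    are the standardized data projected on the loadings.
    """
    X = traits.copy()
    const = [c for c in X.columns if X[c].dropna().nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant traits: {const}", stacklevel=2)
        X = X.drop(columns=const)
    if X.shape[1] < 2:
        raise ValueError("need at least two non-constant traits")
    Xs = (X - X.mean()) / X.std(ddof=1)
    corr = Xs.corr()
    vals, vecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    comp = [f"PC{i + 1}" for i in range(len(vals))]
    loadings = pd.DataFrame(vecs, index=corr.index, columns=comp)
    scores = pd.DataFrame(
        Xs.fillna(0.0).to_numpy() @ vecs, index=X.index, columns=comp
    )
    explained = pd.Series(vals / vals.sum(), index=comp, name="explained")
    return PcaResult(scores, loadings, explained)


# ------------------------------------------------------------------ clustering

def ward_cluster(traits: pd.DataFrame) -> np.ndarray:
    """Ward minimum-variance linkage on standardized traits."""
    X = traits.dropna()
    if len(X) < 2:
        raise ValueError("need at least two complete rows to cluster")
    Xs = (X - X.mean()) / X.std(ddof=1).replace(0.0, 1.0)
    return hierarchy.linkage(Xs.to_numpy(), method="ward")


def flat_clusters(link: np.ndarray, index: pd.Index, k: int) -> pd.Series:
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=index[: len(labels)], name="cluster")


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Newick-style text export of a scipy linkage."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def pearson_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between traits."""
    return traits.corr(method="pearson")
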