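"""REML variance components and BLUPs for the non-replicated augmented design.

Model (single year)::

    y = mu + check + u_genotype + u_row + u_col + e

with the replicated check cultivars as fixed effects and genotype, row and
column as independent random intercepts.  The across-years fit adds year as
a fixed effect, keeps one genotype effect across years, nests row/column
effects within year, and adds a genotype-by-year interaction component.

Variance components are estimated by REML with the residual variance
profiled out: the restricted likelihood is maximized over the variance
ratios gamma_i = sigma2_i / sigma2_e (bounded below by zero, so components
are never negative), and BLUPs solve the mixed-model equations at the
estimates.  Replicated checks are what makes sigma2_e identifiable in an
unreplicated design, so a fit without any replicated entry is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponents:
    sigma2_genotype: float
    sigma2_row: float
    sigma2_column: float
    sigma2_residual: float
    sigma2_gxy: float | None = None
    reml_loglik: float = np.nan

    def as_dict(self) -> dict:
        d = {
            "sigma2_genotype": self.sigma2_genotype,
            "sigma2_row": self.sigma2_row,
            "sigma2_column": self.sigma2_column,
            "sigma2_residual": self.sigma2_residual,
            "reml_loglik": self.reml_loglik,
        }
        if self.sigma2_gxy is not None:
            d["sigma2_gxy"] = self.sigma2_gxy
        return d


@dataclass
class AugmentedFit:
    components: VarianceComponents
    blups: pd.Series          # genotypic value: baseline + genotype effect
    effects: pd.Series        # the random genotype effect itself
    baseline: float


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels.dropna()))
    idx = {l: j for j, l in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, l in enumerate(labels):
        if not pd.isna(l):
            Z[i, idx[l]] = 1.0
    return Z, levels


def build_design(df: pd.DataFrame, across_years: bool = False):
    """Model matrices from a tidy observation frame.

    Requires columns genotype, row, col, is_check, value (and year for the
    across-years fit).  Random genotype effects are fitted for test entries
    only; check plots enter through their fixed check-cultivar effect.
    """
    df = df.loc[df["value"].notna()].reset_index(drop=True)
    if df.empty:
        raise ValueError("no non-missing observations")
    y = df["value"].to_numpy(dtype=float)
    n = len(df)

    cols = [np.ones(n)]
    checks = sorted(df.loc[df["is_check"], "genotype"].unique())
    for c in checks:
        cols.append(((df["genotype"] == c) & df["is_check"]).to_numpy(float))
    if across_years:
        years = sorted(df["year"].unique())
        for yv in years[1:]:
            cols.append((df["year"] == yv).to_numpy(float))
    X = np.column_stack(cols)

    test_geno = df["genotype"].where(~df["is_check"])
    Zg, geno_levels = _indicator(test_geno)
    if across_years:
        rowlab = df["year"].astype(str) + ":" + df["row"].astype(str)
        collab = df["year"].astype(str) + ":" + df["col"].astype(str)
        gylab = test_geno.astype("string") + ":" + df["year"].astype(str)
        gylab = gylab.where(test_geno.notna())
    else:
        rowlab, collab, gylab = df["row"], df["col"], None
    Zr, _ = _indicator(rowlab)
    Zc, _ = _indicator(collab)
    Zs = {"genotype": Zg, "row": Zr, "column": Zc}
    if gylab is not None:
        Zgy, _ = _indicator(gylab)
        Zs["gxy"] = Zgy
    return y, X, Zs, geno_levels, df


def _reml_neg2(gammas, y, X, Zmats):
    """-2 * restricted log-likelihood with sigma2_e profiled out."""
    n, p = X.shape
    V0 = np.eye(n)
    for g, Z in zip(gammas, Zmats):
        if g > 0:
            V0 += g * (Z @ Z.T)
    try:
        cf = linalg.cho_factor(V0, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = linalg.cho_solve(cf, X)
    Vi_y = linalg.cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cf, r))
    if quad <= 0:
        return np.inf
    s2e = quad / (n - p)
    return (n - p) * np.log(s2e) + logdet_V0 + logdet_XtViX + (n - p)


def reml_augmented(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    tol: float = 1e-10,
) -> dict[str, float]:
    """Maximize the restricted likelihood; returns absolute variances + loglik."""
    names = list(Zs)
    Zmats = [Zs[k] for k in names]
    n, p = X.shape
    vary = float(np.var(y))
    if vary < 1e-30 or n <= p:
        out = {k: 0.0 for k in names}
        out["residual"] = 0.0
        out["loglik"] = np.nan
        return out

    x0 = np.full(len(names), 0.5)
    res = optimize.minimize(
        _reml_neg2,
        x0,
        args=(y, X, Zmats),
        method="L-BFGS-B",
        bounds=[(0.0, 1e6)] * len(names),
        options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"REML did not converge: {res.message}")
    gammas = res.x
    # residual variance at the profile optimum
    V0 = np.eye(n)
    for g, Z in zip(gammas, Zmats):
        if g > 0:
            V0 += g * (Z @ Z.T)
    cf = linalg.cho_factor(V0, lower=True)
    Vi_X = linalg.cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ linalg.cho_solve(cf, y))
    r = y - X @ beta
    s2e = float(r @ linalg.cho_solve(cf, r)) / (n - p)
    out = {k: float(g * s2e) for k, g in zip(names, gammas)}
    out["residual"] = s2e
    out["loglik"] = -0.5 * (res.fun + (n - p) * _LOG2PI)
    return out


def solve_blups(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    variances: dict[str, float],
    geno_levels: list,
) -> tuple[pd.Series, float]:
    """Random genotype effects and the fixed baseline at given variances.

    Degenerate all-zero variances (perfectly noiseless data) fall back to the
    per-genotype observed mean, the exact BLUP limit.
    """
    n = len(y)
    s2e = variances["residual"]
    total = sum(max(variances[k], 0.0) for k in Zs) + max(s2e, 0.0)
    # (near-)noiseless data: the BLUP limit is the fixed-effect-adjusted
    # per-genotype mean; solving the ill-conditioned MME would only add noise
    if s2e <= 1e-10 * total or total <= 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        Zg = Zs["genotype"]
        counts = Zg.sum(axis=0)
        u = np.divide(Zg.T @ r, counts, out=np.zeros_like(counts), where=counts > 0)
        return pd.Series(u, index=geno_levels), float(beta[0])
    V = s2e * np.eye(n)
    for k, Z in Zs.items():
        if variances[k] > 0:
            V += variances[k] * (Z @ Z.T)
    cf = linalg.cho_factor(V, lower=True)
    Vi_X = linalg.cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ linalg.cho_solve(cf, y))
    r = y - X @ beta
    Vi_r = linalg.cho_solve(cf, r)
    u = variances["genotype"] * (Zs["genotype"].T @ Vi_r)
    # baseline: mean fixed-effect value over test plots (intercept for a
    # single year; intercept + plot-weighted mean year effect across years)
    is_test = Zs["genotype"].sum(axis=1) > 0
    baseline = float(np.mean((X @ beta)[is_test])) if is_test.any() else float(beta[0])
    return pd.Series(u, index=geno_levels), baseline


def _check_replication(df: pd.DataFrame) -> None:
    reps = df.groupby(["genotype"])["value"].count()
    checks = df.loc[df["is_check"], "genotype"].unique()
    if not any(reps.get(c, 0) >= 2 for c in checks):
        raise ValueError(
            "no replicated check entries: residual and genotypic variance "
            "are not identifiable in an unreplicated design"
        )


def fit_augmented(df: pd.DataFrame, across_years: bool = False) -> AugmentedFit:
    """REML fit of one trait's observations; returns components and BLUPs.

    ``df`` is tidy with columns genotype/row/col/is_check/value (+ year for
    ``across_years=True``), one row per plot.
    """
    _check_replication(df)
    y, X, Zs, geno_levels, used = build_design(df, across_years=across_years)
    est = reml_augmented(y, X, Zs)
    u, baseline = solve_blups(y, X, Zs, est, geno_levels)
    comp = VarianceComponents(
        sigma2_genotype=est["genotype"],
        sigma2_row=est["row"],
        sigma2_column=est["column"],
        sigma2_residual=est["residual"],
        sigma2_gxy=est.get("gxy"),
        reml_loglik=est["loglik"],
    )
    blups = (baseline + u).rename("blup")
    blups.index.name = "genotype"
    return AugmentedFit(comp, blups, u.rename("effect"), baseline)


def combine_years(df: pd.DataFrame, method: str = "joint") -> AugmentedFit | pd.Series:
    """Across-years genotypic values.

    ``method="joint"`` (default) refits one mixed model over all years with
    year as an extra fixed effect; ``method="average"`` averages the per-year
    BLUPs instead.
    """
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("across-years fit needs at least two years")
    if method == "joint":
        return fit_augmented(df, across_years=True)
    if method == "average":
        per_year = [
            fit_augmented(df[df["year"] == yv]).blups.rename(yv) for yv in years
        ]
        return pd.concat(per_year, axis=1).mean(axis=1).rename("blup")
    raise ValueError("method must be 'joint' or 'average'")


def blup_table(
    trait_table: pd.DataFrame,
    traits: list[str] | None = None,
    scopes: str = "both",
) -> tuple[pd.DataFrame, dict]:
    """Per-year and across-years BLUPs for every requested trait.

    ``trait_table`` is the tidy output of the trait-derivation step.  Returns
    a tidy frame (genotype, trait, scope, blup) and a nested dict of variance
    components keyed by (trait, scope).
    """
    traits = traits or sorted(trait_table["trait"].unique())
    years = sorted(trait_table["year"].unique())
    rows, comps = [], {}
    for trait in traits:
        sub = trait_table[trait_table["trait"] == trait]
        if scopes in ("year", "both"):
            for yv in years:
                fit = fit_augmented(sub[sub["year"] == yv])
                comps[(trait, str(yv))] = fit.components.as_dict()
                for g, v in fit.blups.items():
                    rows.append(
                        {"genotype": g, "trait": trait, "scope": str(yv), "blup": v}
                    )
        if scopes in ("all", "both") and len(years) >= 2:
            fit = combine_years(sub)
            comps[(trait, "across")] = fit.components.as_dict()
            for g, v in fit.blups.items():
                rows.append(
                    {"genotype": g, "trait": trait, "scope": "across", "blup": v}
                )
    return pd.DataFrame(rows), comps
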