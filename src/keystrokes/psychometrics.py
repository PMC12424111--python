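"""Internal consistency, correlation matrices, descriptives, and the
age + education regression.

Conventions: Pearson correlations use pairwise deletion (each cell is
computed on all cases complete for that pair, so degrees of freedom vary
across cells); regressions use listwise deletion within each model;
standard deviations use the n-1 denominator; significance is flagged at
the .05 and .01 two-tailed levels with no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class UndefinedStatisticError(ValueError):
    """Too few complete cases, or zero variance, to define the statistic."""


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation on complete pairs.

    Two-tailed p from the t statistic r*sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.  Requires at least three complete pairs and
    nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return PearsonResult(float(r), float(p), n)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise-deletion correlation matrix with significance flags."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flag05: pd.DataFrame
    flag01: pd.DataFrame

    def cell(self, a: str, b: str) -> PearsonResult:
        return PearsonResult(float(self.r.loc[a, b]), float(self.p.loc[a, b]),
                             int(self.n.loc[a, b]))

    def flag_glyph(self, a: str, b: str) -> str:
        if bool(self.flag01.loc[a, b]):
            return "**"
        if bool(self.flag05.loc[a, b]):
            return "*"
        return ""


def correlation_matrix(data: pd.DataFrame, variables: list[str] | None = None,
                       ) -> CorrelationMatrix:
    """All pairwise correlations among ``variables`` (default: numeric columns).

    Each cell uses every case complete for that pair, so per-cell n can
    differ (heterogeneous degrees of freedom).  Cells that are undefined
    (fewer than three pairs, or a constant variable) hold NaN.
    """
    if variables is None:
        variables = [c for c in data.columns
                     if pd.api.types.is_numeric_dtype(data[c])]
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i, a in enumerate(variables):
        n[i, i] = int(data[a].notna().sum())
        for j in range(i + 1, k):
            b = variables[j]
            try:
                res = pearson(data[a], data[b])
                r[i, j] = r[j, i] = res.r
                p[i, j] = p[j, i] = res.p
                n[i, j] = n[j, i] = res.n
            except UndefinedStatisticError:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                n[i, j] = n[j, i] = int(
                    (data[a].notna() & data[b].notna()).sum())
    idx = list(variables)
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    ndf = pd.DataFrame(n, index=idx, columns=idx)
    off = ~np.eye(k, dtype=bool)
    flag05 = pd.DataFrame((p < 0.05) & off, index=idx, columns=idx)
    flag01 = pd.DataFrame((p < 0.01) & off, index=idx, columns=idx)
    return CorrelationMatrix(tuple(variables), rdf, pdf, ndf, flag05, flag01)


@dataclass(frozen=True)
class AlphaResult:
    alpha_raw: float | None
    alpha_standardized: float
    k: int
    n: int


def alpha_from_correlations(corr: np.ndarray | pd.DataFrame) -> float:
    """Standardized Cronbach's alpha from a correlation matrix:
    k * rbar / (1 + (k-1) * rbar), rbar the mean off-diagonal correlation."""
    c = np.asarray(corr, dtype=float)
    if c.shape[0] != c.shape[1] or c.shape[0] < 2:
        raise ValueError("need a square correlation matrix of at least 2 items")
    k = c.shape[0]
    off = c[~np.eye(k, dtype=bool)]
    rbar = float(np.mean(off))
    return k * rbar / (1.0 + (k - 1) * rbar)


def cronbach_alpha(scores: pd.DataFrame | np.ndarray) -> AlphaResult:
    """Cronbach's alpha of a cases-by-items score matrix (listwise complete).

    Raw alpha: k/(k-1) * (1 - sum of item variances / variance of sums).
    Standardized alpha: from the mean pairwise correlation.  Requires at
    least two items and two complete cases with nonzero total variance.
    """
    m = pd.DataFrame(scores).dropna()
    n, k = m.shape
    if k < 2:
        raise UndefinedStatisticError("alpha needs at least 2 items")
    if n < 2:
        raise UndefinedStatisticError("alpha needs at least 2 complete cases")
    values = m.to_numpy(dtype=float)
    item_var = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("zero variance in total scores")
    raw = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    if (item_var == 0).any():
        raise UndefinedStatisticError("an item has zero variance")
    standardized = alpha_from_correlations(np.corrcoef(values, rowvar=False))
    return AlphaResult(float(raw), float(standardized), k, n)


#: Condition groupings whose internal consistency is reported alongside the
#: whole test: the two speeded conditions, the three inhibition conditions,
#: and the switching condition with its most similar inhibition condition.
CONDITION_GROUPS: dict[str, tuple[str, ...]] = {
    "all": ("k1", "k2", "k3", "k4", "k5", "k6"),
    "speeded": ("k1", "k2"),
    "inhibition": ("k3", "k4", "k5"),
    "switching": ("k5", "k6"),
}


def group_alphas(data: pd.DataFrame) -> dict[str, AlphaResult]:
    """Whole-test and condition-group alphas of the six subtest scores."""
    return {name: cronbach_alpha(data[list(cols)])
            for name, cols in CONDITION_GROUPS.items()}


@dataclass(frozen=True)
class Coefficient:
    name: str
    estimate: float
    se: float
    t: float
    p: float


@dataclass(frozen=True)
class RegressionFit:
    outcome: str
    coefficients: tuple[Coefficient, ...]
    f: float
    df1: int
    df2: int
    f_p: float
    r2: float
    n: int

    def coefficient(self, name: str) -> Coefficient:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)


def regress_age_education(data: pd.DataFrame, outcome: str) -> RegressionFit:
    """OLS of one subtest score on age and education, with intercept.

    Listwise deletion; reports per-predictor two-tailed p, the overall
    F(2, n-3) test, and R^2.  A collinear design is rejected.
    """
    cols = [outcome, "age", "education"]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    d = data[cols].dropna()
    n = len(d)
    if n < 4:
        raise UndefinedStatisticError(f"need >= 4 complete cases, got {n}")
    X = sm.add_constant(d[["age", "education"]].to_numpy(dtype=float),
                        has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UndefinedStatisticError("collinear predictors (design not full rank)")
    y = d[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    names = ("intercept", "age", "education")
    coeffs = tuple(
        Coefficient(nm, float(fit.params[i]), float(fit.bse[i]),
                    float(fit.tvalues[i]), float(fit.pvalues[i]))
        for i, nm in enumerate(names)
    )
    if np.ptp(y) == 0:
        # constant outcome: zero model and residual SS, define F = R2 = 0
        f, f_p, r2 = 0.0, 1.0, 0.0
    else:
        f = float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0
        f_p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
        r2 = float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0
    return RegressionFit(
        outcome=outcome, coefficients=coeffs,
        f=f, df1=int(fit.df_model), df2=int(fit.df_resid), f_p=f_p,
        r2=r2, n=n,
    )


def descriptives(data: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """N / mean / SD / min / max for numeric columns; frequencies for
    categorical ones.  SD of a single observation reports 0."""
    num_rows = []
    freq: dict[str, pd.Series] = {}
    for col in data.columns:
        if col == "id":
            continue
        s = data[col]
        if pd.api.types.is_numeric_dtype(s):
            v = s.dropna()
            sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
            num_rows.append({
                "variable": col, "N": int(len(v)),
                "M": float(v.mean()) if len(v) else np.nan,
                "SD": sd,
                "min": float(v.min()) if len(v) else np.nan,
                "max": float(v.max()) if len(v) else np.nan,
            })
        else:
            freq[col] = s.value_counts(dropna=False)
    numeric = pd.DataFrame(num_rows).set_index("variable") if num_rows else pd.DataFrame()
    return {"numeric": numeric, **{f"freq_{k}": v.to_frame("N") for k, v in freq.items()}}
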