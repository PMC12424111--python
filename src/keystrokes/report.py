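"""Analysis-report tables for a cohort: descriptives, the subtest
correlation matrix, external-measure and demographic correlations, and
the age + education regressions.

Cells carry the conventional significance glyphs (* for p < .05, ** for
p < .01, two-tailed, uncorrected) and correlations are rounded to two
decimals for display; full precision stays in the underlying
CorrelationMatrix / RegressionFit objects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .psychometrics import (
    CONDITION_GROUPS,
    CorrelationMatrix,
    correlation_matrix,
    descriptives,
    group_alphas,
    regress_age_education,
)
from .simulator import MEASURE_NAMES, CohortTable

SUBTESTS = ("k1", "k2", "k3", "k4", "k5", "k6")

#: Documented default numeric coding for the binary gender variable.
GENDER_CODING = {"female": 0, "male": 1}


def _fmt_r(r: float, glyph: str) -> str:
    if np.isnan(r):
        return "NA"
    return f"{r:.2f}{glyph}"


def table_demographics(cohort: CohortTable) -> pd.DataFrame:
    """Descriptive statistics: N/M/SD/min/max for numeric variables."""
    return descriptives(cohort.data)["numeric"].round(2)


def table_subtest_correlations(cohort: CohortTable) -> pd.DataFrame:
    """Six-by-six subtest correlation matrix with significance glyphs."""
    cm = correlation_matrix(cohort.data, list(SUBTESTS))
    out = pd.DataFrame(index=list(SUBTESTS), columns=list(SUBTESTS), dtype=object)
    for a in SUBTESTS:
        for b in SUBTESTS:
            out.loc[a, b] = "" if a == b else _fmt_r(
                cm.r.loc[a, b], cm.flag_glyph(a, b))
    return out


def table_external_correlations(cohort: CohortTable,
                                measures: tuple[str, ...] = MEASURE_NAMES,
                                ) -> pd.DataFrame:
    """Subtest-by-measure correlations (pairwise deletion, varying n)."""
    present = [m for m in measures if m in cohort.data.columns]
    cm = correlation_matrix(cohort.data, list(SUBTESTS) + present)
    rows = []
    for k in SUBTESTS:
        row: dict = {"subtest": k.upper()}
        for m in present:
            row[m] = _fmt_r(cm.r.loc[k, m], cm.flag_glyph(k, m))
            row[f"{m}_n"] = int(cm.n.loc[k, m])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtest")


def table_demographic_correlations(cohort: CohortTable,
                                   ethnicity_coding: dict[str, float] | None = None,
                                   gender_coding: dict[str, float] | None = None,
                                   ) -> pd.DataFrame:
    """Subtest correlations with age, education, gender, and (optionally)
    ethnicity.

    Ethnicity is categorical with no privileged order, so it is only
    correlated when the caller supplies an explicit numeric coding; there
    is deliberately no default.  Gender uses the documented binary coding
    unless overridden.
    """
    d = cohort.data.copy()
    demo_cols = ["age", "education"]
    gc = GENDER_CODING if gender_coding is None else gender_coding
    if "gender" in d.columns:
        d["gender_coded"] = d["gender"].map(gc)
        demo_cols.append("gender_coded")
    if ethnicity_coding is not None:
        unknown = set(d["ethnicity"].dropna()) - set(ethnicity_coding)
        if unknown:
            raise ValueError(f"ethnicity coding missing categories: {sorted(unknown)}")
        d["ethnicity_coded"] = d["ethnicity"].map(ethnicity_coding)
        demo_cols.append("ethnicity_coded")
    cm = correlation_matrix(d, list(SUBTESTS) + demo_cols)
    rows = []
    for k in SUBTESTS:
        row: dict = {"subtest": k.upper()}
        for c in demo_cols:
            label = c.replace("_coded", "")
            row[label] = _fmt_r(cm.r.loc[k, c], cm.flag_glyph(k, c))
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtest")


def table_regressions(cohort: CohortTable) -> pd.DataFrame:
    """Age + education OLS summary per subtest, in the reporting format
    'F(df1, df2) = x, p = y, R^2 = z' plus per-predictor p values."""
    rows = []
    for k in SUBTESTS:
        fit = regress_age_education(cohort.data, k)
        rows.append({
            "subtest": k.upper(),
            "age_p": round(fit.coefficient("age").p, 4),
            "education_p": round(fit.coefficient("education").p, 4),
            "F": round(fit.f, 2),
            "df1": fit.df1,
            "df2": fit.df2,
            "overall_p": round(fit.f_p, 4),
            "R2": round(fit.r2, 2),
        })
    return pd.DataFrame(rows).set_index("subtest")


def table_alphas(cohort: CohortTable) -> pd.DataFrame:
    """Whole-test and condition-group internal consistency."""
    rows = []
    for name, res in group_alphas(cohort.data[list(SUBTESTS)]).items():
        rows.append({
            "group": name,
            "items": ",".join(CONDITION_GROUPS[name]),
            "alpha_raw": round(res.alpha_raw, 2),
            "alpha_standardized": round(res.alpha_standardized, 2),
            "k": res.k,
            "n": res.n,
        })
    return pd.DataFrame(rows).set_index("group")


def render_text(df: pd.DataFrame, title: str) -> str:
    """Aligned plain-text rendering of a report table."""
    return f"{title}\n{'-' * len(title)}\n{df.to_string()}\n"


def write_report(cohort: CohortTable, out_dir: str | Path,
                 ethnicity_coding: dict[str, float] | None = None) -> dict[str, Path]:
    """Write all report tables as CSV plus one aligned-text digest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "table1_demographics": table_demographics(cohort),
        "table2_subtest_correlations": table_subtest_correlations(cohort),
        "table3_external_correlations": table_external_correlations(cohort),
        "table4_demographic_correlations": table_demographic_correlations(
            cohort, ethnicity_coding=ethnicity_coding),
        "table5_regressions": table_regressions(cohort),
        "alphas": table_alphas(cohort),
    }
    paths: dict[str, Path] = {}
    digest = []
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p)
        paths[name] = p
        digest.append(render_text(df, name))
    text_path = out_dir / "report.txt"
    text_path.write_text("\n".join(digest), encoding="utf-8")
    paths["report_text"] = text_path
    return paths
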