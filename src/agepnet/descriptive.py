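"""Demographic summary tables with between-stratum tests.

Produces the classic cohort-characteristics table: counts and percentages
for categorical rows, mean (SD) and median (IQR) for age and drugs per
report, with a chi-squared test for categorical characteristics and a
Welch two-sample t-test for numeric ones between the two named strata.
Percentages use known-value denominators where a characteristic has an
unknown level (reporter type, seriousness); reports with unknown stratum
appear in the overall column but are excluded from the comparison.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import AGE_GROUPS, REGIONS, REPORTER_TYPES, ReportSet

#: characteristics whose percentages are computed over known values only
_KNOWN_DENOMINATOR = {"reporter", "serious"}


def _reports_frame(report_set: ReportSet) -> pd.DataFrame:
    rows = [
        {
            "age": r.age_years,
            "age_group": r.age_group,
            "sex": r.sex,
            "region": r.region,
            "reporter": r.reporter,
            "serious": r.serious,
            "death": r.death,
            "n_drugs": r.n_drugs,
        }
        for r in report_set.reports
    ]
    return pd.DataFrame(rows)


def _stratum_column(df: pd.DataFrame, strata: str) -> pd.Series:
    if strata == "sex":
        return df["sex"].where(df["sex"].isin(["female", "male"]))
    if strata == "age65":
        out = pd.Series(pd.NA, index=df.index, dtype=object)
        known = df["age"].notna()
        out[known & (df["age"] >= 65)] = "65+"
        out[known & (df["age"] < 65)] = "<65"
        return out
    raise ValueError(f"strata must be 'sex', 'age65' or 'none', got {strata!r}")


def chi_squared(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a contingency table.

    No continuity correction by default (tables larger than 2x2 never use
    one); ``yates=True`` applies the Yates correction on 2x2 tables.
    """
    table = np.asarray(table, dtype=float)
    correction = bool(yates) and table.shape == (2, 2)
    stat, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def welch_t(x, y) -> tuple[float, float]:
    """Welch (unequal variances) two-sample t-test; the conservative default."""
    res = sps.ttest_ind(x, y, equal_var=False, nan_policy="omit")
    return float(res.statistic), float(res.pvalue)


def _categorical_rows(
    name: str,
    series: pd.Series,
    levels,
    groups: Optional[dict[str, pd.Series]],
    yates: bool,
) -> list[dict]:
    rows = []
    known_only = name in _KNOWN_DENOMINATOR
    present_levels = [lv for lv in levels if (series == lv).any()]

    def pct(sub: pd.Series, level) -> tuple[int, float]:
        n = int((sub == level).sum())
        denom = int(sub.isin([lv for lv in levels if lv != "unknown"]).sum()) \
            if known_only else int(sub.notna().sum())
        return n, (100.0 * n / denom if denom else np.nan)

    p_value = np.nan
    if groups:
        counting_levels = [
            lv for lv in present_levels
            if not (known_only and lv == "unknown")
        ]
        table = np.array(
            [[int((g == lv).sum()) for lv in counting_levels]
             for g in groups.values()]
        )
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if table.shape[1] >= 2 and table.sum() > 0:
            _, p_value = chi_squared(table, yates=yates)

    for i, lv in enumerate(present_levels):
        row = {"characteristic": name, "level": lv,
               "p_value": p_value if i == 0 else np.nan}
        n, p = pct(series, lv)
        row["overall_n"], row["overall_pct"] = n, p
        if groups:
            for gname, g in groups.items():
                n, p = pct(g, lv)
                row[f"{gname}_n"], row[f"{gname}_pct"] = n, p
        rows.append(row)
    return rows


def _numeric_rows(
    name: str,
    series: pd.Series,
    groups: Optional[dict[str, pd.Series]],
) -> list[dict]:
    def stats_of(s: pd.Series) -> dict:
        s = s.dropna().astype(float)
        if s.empty:
            return {"mean": np.nan, "sd": np.nan, "median": np.nan,
                    "q1": np.nan, "q3": np.nan}
        return {
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            "median": float(s.median()),
            "q1": float(s.quantile(0.25)),
            "q3": float(s.quantile(0.75)),
        }

    p_value = np.nan
    if groups and len(groups) == 2:
        a, b = [g.dropna().astype(float) for g in groups.values()]
        if len(a) > 1 and len(b) > 1:
            if a.nunique() <= 1 and b.nunique() <= 1 and a.mean() == b.mean():
                p_value = 1.0  # identical constant inputs
            else:
                _, p_value = welch_t(a, b)

    row = {"characteristic": name, "level": "", "p_value": p_value}
    overall = stats_of(series)
    row.update({f"overall_{k}": v for k, v in overall.items()})
    if groups:
        for gname, g in groups.items():
            row.update({f"{gname}_{k}": v for k, v in stats_of(g).items()})
    return [row]


def demographics_table(
    report_set: ReportSet,
    strata: str = "sex",
    yates: bool = False,
) -> pd.DataFrame:
    """Cohort characteristics, optionally compared between two strata.

    ``strata`` is ``"sex"`` (female vs male), ``"age65"`` (<65 vs 65+ —
    exactly 65 counts as the older stratum) or ``"none"``.  If a stratum is
    entirely absent the comparison is omitted and the overall summary is
    still produced.
    """
    df = _reports_frame(report_set)
    if df.empty:
        raise ValueError("empty report set")

    groups: Optional[dict[str, pd.Series]] = None
    if strata != "none":
        col = _stratum_column(df, strata)
        names = [g for g in (["female", "male"] if strata == "sex"
                             else ["<65", "65+"]) if (col == g).any()]
        if len(names) == 2:
            groups = {g: df.loc[col == g] for g in names}
        else:
            groups = None

    def grouped(column):
        return {g: sub[column] for g, sub in groups.items()} if groups else None

    rows: list[dict] = []
    rows += _numeric_rows("age", df["age"], grouped("age"))
    rows += _categorical_rows("age_group", df["age_group"], AGE_GROUPS,
                              grouped("age_group"), yates)
    rows += _categorical_rows("sex", df["sex"], ("female", "male", "unknown"),
                              grouped("sex") if strata != "sex" else None,
                              yates)
    rows += _categorical_rows("region", df["region"], REGIONS,
                              grouped("region"), yates)
    rows += _categorical_rows("reporter", df["reporter"],
                              REPORTER_TYPES, grouped("reporter"), yates)

    ser = df["serious"].map({True: "yes", False: "no"}).fillna("unknown")
    ser_groups = (
        {g: sub["serious"].map({True: "yes", False: "no"}).fillna("unknown")
         for g, sub in groups.items()} if groups else None
    )
    rows += _categorical_rows("serious", ser, ("yes", "no", "unknown"),
                              ser_groups, yates)

    death = df["death"].map({True: "yes", False: "no"}).fillna("unknown")
    death_groups = (
        {g: sub["death"].map({True: "yes", False: "no"}).fillna("unknown")
         for g, sub in groups.items()} if groups else None
    )
    rows += _categorical_rows("death", death, ("yes", "no", "unknown"),
                              death_groups, yates)

    rows += _numeric_rows("n_drugs", df["n_drugs"], grouped("n_drugs"))
    return pd.DataFrame(rows)
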