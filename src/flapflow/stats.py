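"""Cohort-level descriptive and univariate statistics.

Implements the statistical machinery of an exploratory clinical series:
continuous variables summarized by median/IQR/range and mean/sd, categorical
ones by counts and percentages; group comparisons of continuous outcomes by
the classical (pooled-variance) two-sample t test or one-way ANOVA for more
than two groups; associations between categorical variables by the
chi-square test when its validity conditions hold (all expected cell counts
at least 5) and Fisher's exact test otherwise.  Significance is declared at
alpha = 0.05 and no multiple-testing correction is applied — the design is
explicitly exploratory, and the univariate report says so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, SchemaError

__all__ = [
    "ComparisonResult",
    "read_cohort",
    "write_cohort",
    "summarize",
    "compare_means",
    "compare_categorical",
    "univariate_table",
    "report_to_markdown",
]

ALPHA = 0.05
MIN_EXPECTED = 5.0  # chi-square validity threshold on expected cell counts


@dataclass
class ComparisonResult:
    """Outcome of one univariate group comparison."""

    group_var: str
    outcome: str
    groups: list[dict]  # each: {"level", "n", "mean"} (categorical: counts)
    test_name: str  # "Student t" | "ANOVA" | "chi-square" | "Fisher exact"
    statistic: float
    p_value: float
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p value {self.p_value} outside [0, 1]")
        self.significant = bool(self.p_value < ALPHA)


def read_cohort(
    path: str | Path,
    mapping: dict[str, str] | None = None,
    required: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Read a per-patient cohort CSV, renaming columns via ``mapping``.

    ``mapping`` maps CSV column names to canonical names (the escape hatch
    for externally produced tables whose headers differ).  Columns listed in
    ``required`` must be present after renaming.

    Raises
    ------
    SchemaError
        Naming any missing mandatory column.
    """
    df = pd.read_csv(path)
    if mapping:
        missing_src = [c for c in mapping if c not in df.columns]
        if missing_src:
            raise SchemaError(f"mapped source columns absent from {path}: {missing_src}")
        df = df.rename(columns=mapping)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table {path} is missing mandatory columns: {missing}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def summarize(df: pd.DataFrame, variable: str, kind: str = "continuous") -> dict:
    """Descriptive summary of one column.

    Continuous: median, IQR, min-max, mean, sd, n.  Categorical: per-level
    counts and percentages of non-missing values.
    """
    if variable not in df.columns:
        raise SchemaError(f"no column {variable!r} in the table")
    col = df[variable].dropna()
    if col.empty:
        raise ParameterError(f"column {variable!r} has no non-missing values")
    if kind == "continuous":
        vals = col.astype(float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {
            "variable": variable,
            "n": int(vals.size),
            "median": float(med),
            "iqr": (float(q1), float(q3)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
        }
    if kind == "categorical":
        counts = col.value_counts()
        n = int(counts.sum())
        return {
            "variable": variable,
            "n": n,
            "levels": [
                {"level": lvl, "count": int(c), "percent": round(100.0 * c / n, 1)}
                for lvl, c in counts.items()
            ],
        }
    raise ParameterError(f"kind must be 'continuous' or 'categorical', got {kind!r}")


def compare_means(
    df: pd.DataFrame,
    outcome: str,
    group: str,
    equal_var: bool = True,
) -> ComparisonResult:
    """Compare outcome means across the levels of a categorical column.

    Two levels: two-sided two-sample t test, pooled variance by default
    (``equal_var=False`` gives Welch).  More than two: one-way ANOVA.
    Complete-case per comparison: rows missing either column are dropped.

    Raises
    ------
    ParameterError
        If fewer than two groups remain or any group has fewer than two
        observations.
    """
    for c in (outcome, group):
        if c not in df.columns:
            raise SchemaError(f"no column {c!r} in the table")
    sub = df[[outcome, group]].dropna()
    levels = sorted(sub[group].unique(), key=str)
    if len(levels) < 2:
        raise ParameterError(f"grouping {group!r} has fewer than two non-empty levels")
    samples = [sub.loc[sub[group] == lvl, outcome].astype(float).to_numpy() for lvl in levels]
    if any(s.size < 2 for s in samples):
        raise ParameterError(f"a level of {group!r} has fewer than two observations")
    if len(levels) == 2:
        stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=equal_var)
        test = "Student t" if equal_var else "Welch t"
    else:
        stat, p = sps.f_oneway(*samples)
        test = "ANOVA"
    groups = [
        {"level": lvl, "n": int(s.size), "mean": float(s.mean())}
        for lvl, s in zip(levels, samples)
    ]
    return ComparisonResult(group, outcome, groups, test, float(stat), float(p))


def _expected_counts(table: np.ndarray) -> np.ndarray:
    total = table.sum()
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / total


def compare_categorical(df: pd.DataFrame, a: str, b: str) -> ComparisonResult:
    """Association between two categorical columns.

    Builds the contingency table, then applies the chi-square test (without
    continuity correction) if every expected count is >= 5, and Fisher's
    exact test otherwise.  Fisher's exact test is available for 2x2 tables;
    a larger sparse table falls back to chi-square with a validity warning.

    Raises
    ------
    ParameterError
        If either variable has a single level after dropping missing rows.
    """
    for c in (a, b):
        if c not in df.columns:
            raise SchemaError(f"no column {c!r} in the table")
    sub = df[[a, b]].dropna()
    table = pd.crosstab(sub[a], sub[b]).to_numpy()
    return _categorical_test(table, a, b)


def _categorical_test(table: np.ndarray, a: str = "rows", b: str = "cols") -> ComparisonResult:
    table = np.asarray(table, dtype=float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ParameterError("both variables need at least two observed levels")
    expected = _expected_counts(table)
    use_fisher = (expected < MIN_EXPECTED).any()
    if use_fisher and table.shape == (2, 2):
        stat, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
        test = "Fisher exact"
    else:
        if use_fisher:
            warnings.warn(
                f"expected counts below {MIN_EXPECTED} in a {table.shape} table; "
                "chi-square validity conditions not met",
                stacklevel=2,
            )
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        test = "chi-square"
    groups = [
        {"level": f"row{i}", "counts": [int(c) for c in row]} for i, row in enumerate(table)
    ]
    return ComparisonResult(a, b, groups, test, float(stat), float(p))


def univariate_table(
    df: pd.DataFrame,
    outcomes: list[str],
    covariates: list[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Univariate outcome-by-covariate comparison matrix.

    One row per covariate level, one pair of columns (group mean, p value)
    per outcome — the layout of an exploratory clinical univariate table.
    The returned frame carries ``attrs['note']`` stating that no
    multiple-testing correction (and no multivariate analysis) is applied.
    """
    records: list[dict] = []
    for cov in covariates:
        results = {out: compare_means(df, out, cov, equal_var=equal_var) for out in outcomes}
        levels = [g["level"] for g in results[outcomes[0]].groups]
        for i, lvl in enumerate(levels):
            rec: dict = {"covariate": cov, "level": lvl,
                         "n": results[outcomes[0]].groups[i]["n"]}
            for out in outcomes:
                rec[f"{out}_mean"] = results[out].groups[i]["mean"]
                # p value printed on the first level row only, as in a report
                rec[f"{out}_p"] = results[out].p_value if i == 0 else np.nan
                rec[f"{out}_significant"] = results[out].significant if i == 0 else None
            records.append(rec)
    report = pd.DataFrame.from_records(records)
    report.attrs["note"] = (
        "Exploratory univariate analysis; no multiple-testing correction applied "
        "and no multivariate analysis performed."
    )
    return report


def report_to_markdown(report: pd.DataFrame) -> str:
    """Render a univariate report as a Markdown table with its note."""

    def fmt(v) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return ""
        if isinstance(v, (float, np.floating)):
            return f"{v:.3g}"
        return str(v)

    cols = list(report.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in report.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    note = report.attrs.get("note")
    if note:
        lines += ["", f"*{note}*"]
    return "\n".join(lines)
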