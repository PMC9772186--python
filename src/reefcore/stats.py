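"""Lineage x habitat trait statistics: cohort join, ANOVA, Tukey, chi-squared.

Joins lineage assignments, per-core growth means (density, extension,
calcification averaged over 1999-2009) and stress-band presence flags into a
cohort table, then computes the group contrasts: one-way ANOVA with post hoc
Tukey HSD for growth metrics, and chi-squared tests on stress-band prevalence
(thermal tolerance) across lineages and habitats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .popgen import ADMIXED

__all__ = [
    "TestResult",
    "build_cohort",
    "one_way_anova",
    "tukey_hsd",
    "prevalence_test",
    "reproduce_report",
]

GROWTH_COLUMNS = (
    "mean_density_g_cm3",
    "mean_calcification_g_cm2_yr",
    "mean_extension_cm",
)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one group-contrast test."""

    name: str  # "F" or "X2"
    statistic: float
    df: float | tuple
    p_value: float
    group_sizes: dict[str, int]
    pairwise: pd.DataFrame | None = field(default=None, repr=False)
    table: pd.DataFrame | None = field(default=None, repr=False)
    warnings: tuple = ()

    def __str__(self) -> str:
        return (
            f"{self.name} = {self.statistic:.4g}, df = {self.df}, "
            f"p = {self.p_value:.4g} (n = {self.group_sizes})"
        )


def build_cohort(
    assignments: pd.Series,
    core_summaries: pd.DataFrame,
    stress_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join lineage, habitat, growth means, and stress flags per colony.

    ``assignments`` maps colony id -> lineage (or "admixed");
    ``core_summaries`` is indexed by id with the growth-mean columns and
    optionally ``habitat``; ``stress_flags`` is indexed by id with one
    boolean/NA column per event year (``stress_1998`` etc., NA when the core
    does not reach the year).  Colonies present in the assignment but lacking
    core data are carried with missing growth fields; admixed colonies are
    retained in the table (downstream tests exclude them).
    """
    if assignments.index.has_duplicates or core_summaries.index.has_duplicates:
        raise ValueError("duplicate colony ids")
    cohort = assignments.rename("lineage").to_frame()
    cohort = cohort.join(core_summaries, how="outer")
    if stress_flags is not None:
        if stress_flags.index.has_duplicates:
            raise ValueError("duplicate colony ids in stress flags")
        cohort = cohort.join(stress_flags, how="left")
    if len(assignments.index.intersection(core_summaries.index)) == 0:
        warnings.warn("cohort join produced no overlapping records", stacklevel=2)
    cohort.index.name = "id"
    return cohort


def _clean_groups(values, groups, min_n: int = 2):
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df.groupby("group").size()
    small = sizes[sizes < min_n].index
    if len(small):
        warnings.warn(f"groups dropped (n < {min_n}): {list(small)}", stacklevel=3)
        df = df[~df["group"].isin(small)]
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups with at least 2 values each")
    return df


def one_way_anova(values, groups) -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    F with between-groups df = k - 1 and within-groups df = N - k; missing
    values dropped; groups with fewer than 2 values dropped with a warning.
    """
    df = _clean_groups(values, groups)
    arrays = [v.to_numpy(dtype=float) for _, v in df.groupby("group")["value"]]
    f, p = sps.f_oneway(*arrays)
    k, n = len(arrays), len(df)
    return TestResult(
        name="F",
        statistic=float(f),
        df=(k - 1, n - k),
        p_value=float(p),
        group_sizes={str(g): int(len(v)) for g, v in df.groupby("group")["value"]},
    )


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer post hoc pairwise comparisons (unequal n allowed).

    Returns one row per group pair with the mean difference, adjusted
    p-value, and a significance flag at ``alpha``.
    """
    df = _clean_groups(values, groups)
    res = pairwise_tukeyhsd(
        df["value"].to_numpy(dtype=float), df["group"].to_numpy(), alpha=alpha
    )
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    frame = frame.rename(
        columns={"group1": "a", "group2": "b", "meandiff": "mean_diff",
                 "p-adj": "p_adj", "reject": "significant"}
    )
    return frame[["a", "b", "mean_diff", "p_adj", "significant"]]


def prevalence_test(
    flags: pd.Series,
    groups: pd.Series,
    yates_2x2: bool = True,
) -> TestResult:
    """Chi-squared test of stress-band prevalence across groups.

    Builds the k x 2 present/absent contingency table over assessable
    colonies (flags not NA), computes Pearson's X2 with df = k - 1 (Yates
    continuity correction applied only to 2 x 2 tables when ``yates_2x2``),
    and reports per-group prevalence fractions.  An expected cell below 1
    attaches a warning but the test is still computed.  A table with no
    variation (all present or all absent) has X2 = 0 by convention.
    """
    df = pd.DataFrame({"flag": flags, "group": groups}).dropna()
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    df["flag"] = df["flag"].astype(bool)
    table = pd.crosstab(df["group"], df["flag"]).reindex(
        columns=[True, False], fill_value=0
    )
    table.columns = ["present", "absent"]
    k = len(table)
    obs = table.to_numpy(dtype=float)
    warns = []
    if obs[:, 0].sum() == 0 or obs[:, 1].sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        correct = yates_2x2 and obs.shape == (2, 2)
        chi2, p, _, expected = sps.chi2_contingency(obs, correction=correct)
        if (expected < 1).any():
            warns.append("expected cell count below 1")
    prevalence = table["present"] / table.sum(axis=1)
    out = table.copy()
    out["prevalence"] = prevalence
    return TestResult(
        name="X2",
        statistic=float(chi2),
        df=k - 1,
        p_value=float(p),
        group_sizes={str(g): int(n) for g, n in table.sum(axis=1).items()},
        table=out,
        warnings=tuple(warns),
    )


def reproduce_report(
    cohort: pd.DataFrame,
    event_years: tuple[int, ...] = (1998, 2010),
    habitat_lineages: tuple[str, ...] = ("DB", "LB"),
    alpha: float = 0.05,
    yates_2x2: bool = True,
) -> dict:
    """Full battery of lineage and lineage x habitat contrasts.

    Emits, keyed by test name: lineage ANOVAs + Tukey tables for the three
    growth metrics; lineage prevalence chi-squared per event year; growth
    ANOVAs + Tukey over lineage-habitat groups for the lineages present in
    both habitats; and per-lineage habitat prevalence chi-squared.  Admixed
    colonies are excluded from all lineage-based tests.
    """
    for col in GROWTH_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    assigned = cohort[cohort["lineage"].notna() & (cohort["lineage"] != ADMIXED)]
    report: dict = {}

    for col in GROWTH_COLUMNS:
        metric = col.removeprefix("mean_").split("_")[0]
        report[f"lineage_anova_{metric}"] = one_way_anova(
            assigned[col], assigned["lineage"]
        )
        report[f"lineage_tukey_{metric}"] = tukey_hsd(
            assigned[col], assigned["lineage"], alpha=alpha
        )

    for year in event_years:
        col = f"stress_{year}"
        if col in assigned.columns and assigned[col].notna().sum() > 0:
            try:
                report[f"lineage_prevalence_{year}"] = prevalence_test(
                    assigned[col], assigned["lineage"], yates_2x2=yates_2x2
                )
            except ValueError as err:
                warnings.warn(f"prevalence test {year} skipped: {err}", stacklevel=2)

    if "habitat" in assigned.columns:
        both = assigned[assigned["lineage"].isin(habitat_lineages)].copy()
        if not both.empty and both["habitat"].nunique() == 2:
            both["group"] = both["lineage"].astype(str) + ":" + both["habitat"].astype(str)
            if both["group"].nunique() >= 2:
                for col in GROWTH_COLUMNS:
                    metric = col.removeprefix("mean_").split("_")[0]
                    report[f"habitat_anova_{metric}"] = one_way_anova(
                        both[col], both["group"]
                    )
                    report[f"habitat_tukey_{metric}"] = tukey_hsd(
                        both[col], both["group"], alpha=alpha
                    )
            for year in event_years:
                col = f"stress_{year}"
                if col not in both.columns:
                    continue
                for lineage in habitat_lineages:
                    sub = both[both["lineage"] == lineage]
                    if sub[col].notna().sum() == 0 or sub["habitat"].nunique() < 2:
                        continue
                    report[f"habitat_prevalence_{year}_{lineage}"] = prevalence_test(
                        sub[col], sub["habitat"], yates_2x2=yates_2x2
                    )
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a report dict of TestResults into a machine-readable table."""
    rows = []
    for name, res in report.items():
        if isinstance(res, TestResult):
            rows.append(
                {
                    "test": name,
                    "statistic_name": res.name,
                    "statistic": res.statistic,
                    "df": str(res.df),
                    "p_value": res.p_value,
                    "n": sum(res.group_sizes.values()),
                }
            )
    return pd.DataFrame(rows)


def report_to_text(report: dict) -> str:
    """Human-readable report summary."""
    lines = []
    for name, res in report.items():
        if isinstance(res, TestResult):
            lines.append(f"{name}: {res}")
            if res.table is not None:
                lines.append(res.table.to_string())
        else:
            lines.append(f"{name}:")
            lines.append(res.to_string(index=False))
        lines.append("")
    return "\n".join(lines)
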