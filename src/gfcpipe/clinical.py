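"""Demographic/clinical group comparisons and clinical correlations.

Covers the cohort-description statistics (one-way ANOVA for continuous
variables across three groups — also reconstructable from printed
mean/SD/n summaries — a chi-square test of gender distribution, and a
pooled two-sample t-test for illness duration between the patient groups)
and Pearson correlations between regional mean GFC z-values and clinical
scores with Benjamini-Hochberg correction inside an explicitly declared
family of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import bh_adjusted_p, fdr_bh


class ClinicalStatsError(ValueError):
    pass


@dataclass
class GroupSummary:
    """Printed-table style per-group summary of one variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ClinicalStatsError("summary needs n >= 2")
        if self.sd < 0:
            raise ClinicalStatsError("SD must be nonnegative")


@dataclass
class CorrelationResult:
    region: str
    variable: str
    subset: str
    r: float
    p: float
    p_bh: float
    significant: bool
    n: int


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def oneway_anova(values, group_labels) -> tuple[float, float, tuple[int, int]]:
    """One-way ANOVA across groups. Returns (F, p, (df_between, df_within))."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ClinicalStatsError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ClinicalStatsError("every group needs n >= 2")
    df = (len(groups) - 1, values.size - len(groups))
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    if ssb == 0:  # no between-group variance: F is exactly 0 even if SSw = 0
        return 0.0, 1.0, df
    with np.errstate(invalid="ignore"):
        f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # SSw = 0 with SSb > 0
        return float("inf"), 0.0, df
    return float(f), float(p), df


def anova_from_summary(summaries: list[GroupSummary]) -> tuple[float, float]:
    """One-way ANOVA F reconstructed from per-group (mean, SD, n).

    SSb = sum n_g (m_g - grand_mean)^2, SSw = sum (n_g - 1) SD_g^2,
    F = (SSb/(g-1)) / (SSw/(N-g)).  A zero within-group SS with a positive
    between-group SS yields an infinite F.
    """
    if len(summaries) < 2:
        raise ClinicalStatsError("need at least two group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1 = len(summaries) - 1
    df2 = int(n_total) - len(summaries)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def chisq_independence(contingency_table) -> tuple[float, float, int]:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(contingency_table, dtype=np.float64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ClinicalStatsError("contingency table must be at least 2x2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ClinicalStatsError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ClinicalStatsError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), int(df)


def two_sample_t(x, y) -> tuple[float, float, int]:
    """Pooled-variance (Student) two-sample t-test. df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ClinicalStatsError("each sample needs n >= 2")
    df = x.size + y.size - 2
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, df
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0, df
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p), df


def two_sample_t_from_summary(s1: GroupSummary, s2: GroupSummary) -> tuple[float, float, int]:
    """Pooled two-sample t from printed (mean, SD, n) summaries."""
    df = s1.n + s2.n - 2
    if s1.sd == 0 and s2.sd == 0:
        if s1.mean == s2.mean:
            return 0.0, 1.0, df
        return float(np.sign(s1.mean - s2.mean) * np.inf), 0.0, df
    t, p = stats.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=True
    )
    return float(t), float(p), df


# ---------------------------------------------------------------------------
# Clinical correlations
# ---------------------------------------------------------------------------

def pearson_with_bh(
    region_values: pd.DataFrame,
    clinical: pd.DataFrame,
    subset: str = "all",
    q: float = 0.05,
) -> list[CorrelationResult]:
    """Pearson correlations between regions and clinical variables, BH-corrected.

    `region_values` (subjects x regions) and `clinical` (subjects x
    variables) must share their index.  The BH family is all region x
    variable pairs computed in this call for the given subject subset;
    pairs with fewer than 4 complete observations or zero variance are
    skipped with a warning and do not enter the family.
    """
    if not region_values.index.equals(clinical.index):
        raise ClinicalStatsError("region and clinical tables must share subjects")
    results: list[CorrelationResult] = []
    ps: list[float] = []
    for region in region_values.columns:
        for var in clinical.columns:
            pair = pd.concat([region_values[region], clinical[var]], axis=1).dropna()
            x = pair.iloc[:, 0].to_numpy(float)
            y = pair.iloc[:, 1].to_numpy(float)
            if x.size < 4:
                warnings.warn(f"skipping {region} x {var}: n < 4")
                continue
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"skipping {region} x {var}: zero variance")
                continue
            r, p = stats.pearsonr(x, y)
            results.append(CorrelationResult(region, str(var), subset,
                                             float(r), float(p), np.nan, False, x.size))
            ps.append(float(p))
    if results:
        p_arr = np.array(ps)
        reject, _ = fdr_bh(p_arr, q)
        adj = bh_adjusted_p(p_arr)
        for res, rej, pa in zip(results, reject, adj):
            res.significant = bool(rej)
            res.p_bh = float(pa)
    return results


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    rows = [
        {
            "region": r.region,
            "variable": r.variable,
            "subset": r.subset,
            "n": r.n,
            "r": r.r,
            "p": r.p,
            "p_bh": r.p_bh,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["region", "variable", "subset", "n",
                                       "r", "p", "p_bh", "significant"])


def summarize_by_group(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> dict[str, GroupSummary]:
    """Per-group (mean, SD, n) summaries of one variable, ignoring missing."""
    out = {}
    for g, sub in table.groupby(group_col, sort=True):
        v = sub[variable].dropna().to_numpy(float)
        if v.size >= 2:
            out[str(g)] = GroupSummary(float(v.mean()), float(v.std(ddof=1)), v.size)
    return out
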