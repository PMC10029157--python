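"""Nonparametric statistics for lineage-stratified comparisons.

The comparisons reported for O- versus M-lineage KRTAPs are rank-based:
Mann-Whitney rank-sum tests for two groups (protein lengths, skin
expression), Kruskal-Wallis ("ANOVA on ranks") for several, a pooled
two-proportion z-test for tissue-specificity fractions, and median/IQR
summaries.  scipy.stats supplies the distributions; this module fixes the
conventions (two-sided everywhere, exact Mann-Whitney p by enumeration for
small tie-free samples, tie- and continuity-corrected normal approximation
otherwise, inclusive linear-interpolation quartiles) and packages results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Largest per-group size at which the exact (enumeration) Mann-Whitney
#: null distribution is used (given no ties).
EXACT_LIMIT = 8


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q25: float
    q75: float


@dataclass(frozen=True)
class RankTestResult:
    U: float           # U statistic of the first group
    z: float           # normal-approximation z (0.0 when exact method used)
    p_two_sided: float
    method: str        # "exact" or "normal_approx"
    groups: tuple[GroupSummary, ...]


@dataclass(frozen=True)
class PropTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    z: float
    p_two_sided: float


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q25, q75) with midpoint median and inclusive linear
    interpolation between order statistics for the quartiles."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    return (
        float(np.median(v)),
        float(np.quantile(v, 0.25, method="linear")),
        float(np.quantile(v, 0.75, method="linear")),
    )


def _summary(values) -> GroupSummary:
    med, q25, q75 = median_iqr(values)
    return GroupSummary(n=len(values), median=med, q25=q25, q75=q75)


def mann_whitney(x, y, exact_limit: int = EXACT_LIMIT,
                 continuity: bool = True) -> RankTestResult:
    """Two-sided Mann-Whitney rank-sum test.

    U is computed from midranks.  The exact null distribution (full
    enumeration over rank assignments) is used when both samples have at
    most `exact_limit` observations and there are no ties; otherwise the
    normal approximation with tie correction and (by default) continuity
    correction.  U_x + U_y = n_x * n_y always holds.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    exact = (not ties) and x.size <= exact_limit and y.size <= exact_limit
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    z = 0.0
    if not exact:
        n1, n2 = x.size, y.size
        mu = n1 * n2 / 2.0
        all_vals = np.concatenate([x, y])
        _, tie_counts = np.unique(all_vals, return_counts=True)
        n = n1 + n2
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        sigma = math.sqrt(sigma2) if sigma2 > 0 else float("nan")
        diff = res.statistic - mu
        if continuity and sigma > 0:
            diff -= 0.5 * np.sign(diff)
        z = float(diff / sigma) if sigma > 0 else 0.0
    return RankTestResult(
        U=float(res.statistic),
        z=z,
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
        groups=(_summary(x), _summary(y)),
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p on k-1 df.

    The paper-style "ANOVA on ranks" for more than two groups; for k = 2 it
    is consistent with the Mann-Whitney normal approximation up to
    continuity handling.  All-identical data give H = 0, p = 1.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if len(np.unique(np.concatenate(groups))) == 1:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def two_proportion_z(k1: int, n1: int, k2: int, n2: int,
                     continuity: bool = False) -> PropTestResult:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    continuity correction off by default (the textbook pooled z).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        z = 0.0
    else:
        diff = p1 - p2
        if continuity:
            cc = 0.5 * (1 / n1 + 1 / n2)
            diff = np.sign(diff) * max(abs(diff) - cc, 0.0)
        z = float(diff / math.sqrt(var))
    p = float(2 * sps.norm.sf(abs(z)))
    return PropTestResult(k1=k1, n1=n1, k2=k2, n2=n2, z=z,
                          p_two_sided=min(p, 1.0))


def compare_expression_by_lineage(expression: pd.DataFrame,
                                  labels: dict[str, str],
                                  aggregate: str = "total",
                                  family_of: dict[str, str] | None = None,
                                  leave_out_family: str | None = None) -> dict:
    """Lineage comparison of per-gene aggregate expression.

    `expression` is a genes x samples table of nonnegative values; the
    per-gene aggregate (``"total"`` = row sum, ``"mean"`` = row mean, or a
    column name already present) is compared across lineages: per-lineage
    median/IQR plus a Mann-Whitney test for two lineages or Kruskal-Wallis
    for more.  Lineages with fewer than two labelled genes are skipped with
    a warning.  With `family_of`/`leave_out_family` the comparison is rerun
    with one gene family removed from its lineage (the family-robustness
    check).
    """
    if (expression.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    if aggregate == "total":
        agg = expression.sum(axis=1)
    elif aggregate == "mean":
        agg = expression.mean(axis=1)
    elif aggregate in expression.columns:
        agg = expression[aggregate]
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")

    genes = [g for g in expression.index if g in labels]
    if leave_out_family is not None:
        if family_of is None:
            raise ValueError("leave_out_family requires family_of")
        genes = [g for g in genes if family_of.get(g) != leave_out_family]

    by_lineage: dict[str, list[float]] = {}
    for g in genes:
        by_lineage.setdefault(labels[g], []).append(float(agg.loc[g]))
    kept = {}
    for lin, vals in sorted(by_lineage.items()):
        if len(vals) < 2:
            warnings.warn(f"lineage {lin!r} has < 2 genes; skipped")
            continue
        kept[lin] = vals
    if len(kept) < 2:
        raise ValueError("need >= 2 lineages with >= 2 genes each")

    report: dict = {
        "aggregate": aggregate,
        "quartile_method": "inclusive_linear",
        "sidedness": "two-sided",
        "groups": {
            lin: _summary(vals).__dict__ for lin, vals in kept.items()
        },
    }
    names = list(kept)
    if len(kept) == 2:
        res = mann_whitney(kept[names[0]], kept[names[1]])
        report["test"] = "mann_whitney"
        report["U"] = res.U
        report["p"] = res.p_two_sided
        report["method"] = res.method
    else:
        h, p = kruskal_wallis(list(kept.values()))
        report["test"] = "kruskal_wallis"
        report["H"] = h
        report["p"] = p
    return report
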