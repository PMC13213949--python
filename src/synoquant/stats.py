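"""Normality-gated group statistics and below-LOD analyte handling.

The reporting scheme: every group is Shapiro-Wilk-tested at alpha = 0.05;
only if *all* groups pass is the parametric path taken (Welch t-test for two
groups, one-way ANOVA with Tukey HSD for three or more) and descriptives
reported as mean +/- SD.  Otherwise the non-parametric path is used
(Mann-Whitney rank-sum for two groups, Kruskal-Wallis with Dunn's post-hoc
test and Bonferroni adjustment for more) with median [Q1-Q3] descriptives.
Groups too small (n < 3) or degenerate (zero spread) make the gate
indeterminate and route to the non-parametric path.

Analyte concentrations below their assay's limit of detection (strictly
``value < lod``) are censored; analytes censored in every sample are
excluded from testing and listed in a dedicated below-LOD report block.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "GroupDescriptive",
    "DescribeResult",
    "describe",
    "PairwiseComparison",
    "StatResult",
    "compare_groups",
    "compare_group_values",
    "dunn_test",
    "censor_below_lod",
    "CensorResult",
    "compare_analytes",
]

ALPHA = 0.050


# ---------------------------------------------------------------- descriptives


@dataclass
class GroupDescriptive:
    group: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    shapiro_p: float  # NaN when indeterminate
    normal: "bool | None"  # None = gate indeterminate (n < 3 or degenerate)

    def formatted(self, form: str) -> str:
        if form == "mean_sd":
            return f"{self.mean:.4g} ± {self.sd:.4g}"
        return f"{self.median:.4g} [{self.q1:.4g}–{self.q3:.4g}]"


@dataclass
class DescribeResult:
    per_group: dict[str, GroupDescriptive]
    form: str  # "mean_sd" if every group passed normality, else "median_iqr"

    @property
    def all_normal(self) -> bool:
        return all(d.normal is True for d in self.per_group.values())


def _describe_one(name: str, values: np.ndarray, alpha: float) -> GroupDescriptive:
    values = np.asarray(values, dtype=float)
    n = len(values)
    q1, med, q3 = (
        (np.percentile(values, [25, 50, 75], method="linear"))
        if n
        else (math.nan, math.nan, math.nan)
    )
    mean = float(np.mean(values)) if n else math.nan
    sd = float(np.std(values, ddof=1)) if n > 1 else (0.0 if n == 1 else math.nan)
    if n < 3 or np.ptp(values) == 0:
        shapiro_p, normal = math.nan, None
    else:
        shapiro_p = float(sps.shapiro(values).pvalue)
        normal = shapiro_p > alpha
    return GroupDescriptive(
        group=name, n=n, mean=mean, sd=sd,
        median=float(med), q1=float(q1), q3=float(q3),
        shapiro_p=shapiro_p, normal=normal,
    )


def describe(groups: Mapping[str, Sequence[float]], alpha: float = ALPHA) -> DescribeResult:
    """Per-group descriptives with the Shapiro-Wilk reporting gate.

    Quantiles use linear interpolation.  ``form`` is ``"mean_sd"`` only when
    every group's normality test passes; an indeterminate gate (n < 3 or a
    degenerate, zero-spread sample) selects the median/IQR form.
    """
    per_group = {name: _describe_one(name, np.asarray(v), alpha) for name, v in groups.items()}
    form = "mean_sd" if all(d.normal is True for d in per_group.values()) else "median_iqr"
    return DescribeResult(per_group=per_group, form=form)


# ------------------------------------------------------------------ comparisons


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    significant: bool


@dataclass
class StatResult:
    """Outcome of one variable x region group comparison."""

    variable: str
    region: str
    descriptives: DescribeResult
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    alpha: float = ALPHA
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.omnibus_p < self.alpha

    def summary(self) -> str:
        lines = [
            f"{self.variable}"
            + (f" [{self.region}]" if self.region else "")
            + f"  (alpha = {self.alpha:.3f})",
            "-" * 64,
        ]
        form = self.descriptives.form
        label = "mean ± SD" if form == "mean_sd" else "median [IQR]"
        for d in self.descriptives.per_group.values():
            lines.append(f"  {d.group:>6}  n={d.n:<3d} {label}: {d.formatted(form)}")
        lines.append(
            f"  omnibus: {self.omnibus_test}  stat={self.omnibus_statistic:.4g}  "
            f"p={self.omnibus_p:.4g}"
        )
        for pc in self.pairwise:
            star = " *" if pc.significant else ""
            lines.append(
                f"    {pc.group_a} vs {pc.group_b}: p={pc.p_unadjusted:.4g} "
                f"(adj {pc.p_adjusted:.4g}){star}"
            )
        if self.note:
            lines.append(f"  note: {self.note}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": self.variable,
                    "region": self.region,
                    "test": self.omnibus_test,
                    "omnibus_p": self.omnibus_p,
                    "group_a": pc.group_a,
                    "group_b": pc.group_b,
                    "statistic": pc.statistic,
                    "p_unadjusted": pc.p_unadjusted,
                    "p_adjusted": pc.p_adjusted,
                    "significant": pc.significant,
                }
                for pc in self.pairwise
            ]
        )


def dunn_test(groups: Sequence[np.ndarray]) -> list[tuple[int, int, float, float, float]]:
    """Dunn's post-hoc rank comparisons after Kruskal-Wallis.

    For groups i < j returns ``(i, j, z, p_unadjusted, p_bonferroni)``.
    Mean ranks are taken over the pooled sample, the z statistic uses the
    tie-corrected variance ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)``
    with ``T = sum(t^3 - t)`` over tie groups, and the Bonferroni
    adjustment multiplies by the number of pairs (capped at 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start : start + len(g)])))
        sizes.append(len(g))
        start += len(g)
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((i, j, z, p, min(1.0, m * p)))
    return out


def _pooled_t_pairs(groups: list[np.ndarray]) -> dict[tuple[int, int], tuple[float, float]]:
    """Unadjusted pooled-MSE pairwise t statistics (the quantity Tukey HSD
    adjusts); returns ``(t, p)`` per pair with ``df = N - k``."""
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    N = int(sizes.sum())
    mse = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups) / (N - k)
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(mse * (1.0 / sizes[i] + 1.0 / sizes[j]))
        t = (means[i] - means[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.t.sf(abs(t), N - k) if se > 0 else 1.0
        out[(i, j)] = (t, p)
    return out


def compare_group_values(
    groups: Mapping[str, Sequence[float]],
    variable: str = "",
    region: str = "",
    alpha: float = ALPHA,
) -> StatResult:
    """Normality-gated omnibus + post-hoc comparison of named groups.

    All groups normal (Shapiro-Wilk p > 0.05, n >= 3, non-degenerate):
    Welch t-test for two groups, one-way ANOVA with Tukey HSD for three or
    more.  Otherwise: Mann-Whitney rank-sum for two groups, Kruskal-Wallis
    with Dunn/Bonferroni for more.  Pairwise ``significant`` flags are
    Fisher-protected: they require the omnibus p and the adjusted pairwise
    p to both fall below alpha.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    small = [n for n, a in zip(names, arrays) if len(a) < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 values: {small}")
    desc = describe(dict(zip(names, arrays)), alpha=alpha)

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all values identical: nothing to test
        result = StatResult(
            variable, region, desc, "degenerate (constant data)", 0.0, 1.0,
            alpha=alpha, note="all values identical; test skipped-degenerate",
        )
        result.pairwise = [
            PairwiseComparison(names[i], names[j], 0.0, 1.0, 1.0, False)
            for i, j in itertools.combinations(range(len(names)), 2)
        ]
        return result

    parametric = desc.all_normal
    pairwise: list[PairwiseComparison] = []
    if parametric:
        if len(arrays) == 2:
            test = "Welch t-test"
            res = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
            pairwise.append(
                PairwiseComparison(names[0], names[1], stat, p, p, p < alpha)
            )
        else:
            test = "one-way ANOVA + Tukey HSD"
            res = sps.f_oneway(*arrays)
            stat, p = float(res.statistic), float(res.pvalue)
            tukey = sps.tukey_hsd(*arrays)
            raw = _pooled_t_pairs(arrays)
            for i, j in itertools.combinations(range(len(arrays)), 2):
                p_adj = float(tukey.pvalue[i, j])
                t_raw, p_raw = raw[(i, j)]
                pairwise.append(
                    PairwiseComparison(
                        names[i], names[j], t_raw,
                        p_raw, max(p_adj, p_raw),
                        p < alpha and p_adj < alpha,
                    )
                )
    else:
        if len(arrays) == 2:
            test = "Mann-Whitney rank-sum"
            res = sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            pairwise.append(
                PairwiseComparison(names[0], names[1], stat, p, p, p < alpha)
            )
        else:
            test = "Kruskal-Wallis + Dunn (Bonferroni)"
            res = sps.kruskal(*arrays)
            stat, p = float(res.statistic), float(res.pvalue)
            for i, j, z, p_raw, p_adj in dunn_test(arrays):
                pairwise.append(
                    PairwiseComparison(
                        names[i], names[j], z, p_raw, p_adj,
                        p < alpha and p_adj < alpha,
                    )
                )
    return StatResult(
        variable, region, desc, test, stat, p, pairwise=pairwise, alpha=alpha
    )


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    region: "str | None" = None,
    alpha: float = ALPHA,
    value_col: str = "value",
    group_col: str = "group",
) -> StatResult:
    """Run :func:`compare_group_values` on one variable (x region) of a
    long-format measurement table; missing/censored values are dropped
    per group before testing."""
    sel = table[table["variable"] == variable] if "variable" in table.columns else table
    if region is not None and "region" in sel.columns:
        sel = sel[sel["region"] == region]
    if "flag" in sel.columns:
        sel = sel[sel["flag"] != "missing"]
    if "censored" in sel.columns:
        sel = sel[~sel["censored"].astype(bool)]
    groups = {
        str(name): grp[value_col].dropna().to_numpy()
        for name, grp in sel.groupby(group_col, sort=False)
    }
    groups = {n: v for n, v in groups.items() if len(v) > 0}
    return compare_group_values(
        groups, variable=variable, region=region or "", alpha=alpha
    )


# -------------------------------------------------------------- LOD censoring


@dataclass
class CensorResult:
    """Below-limit-of-detection bookkeeping for an analyte table."""

    table: pd.DataFrame  # original rows + boolean "censored" column
    fully_censored: list[str]  # analytes below LOD in 100 % of samples
    censored_fraction: dict[str, float]

    def testable(self) -> pd.DataFrame:
        """Rows eligible for statistics: censored rows and fully censored
        analytes removed (complete-case)."""
        t = self.table
        return t[~t["censored"] & ~t["analyte"].isin(self.fully_censored)]

    def below_lod_report(self) -> dict:
        return {
            "below_lod_analytes": list(self.fully_censored),
            "censored_fraction": dict(self.censored_fraction),
        }


def censor_below_lod(
    analytes: pd.DataFrame, lod: "Mapping[str, float] | None" = None
) -> CensorResult:
    """Flag analyte values strictly below their limit of detection.

    ``analytes`` is a long table with at least ``analyte`` and ``value``
    columns; detection limits come from ``lod`` or from an ``lod`` column.
    A value exactly equal to the LOD is *not* censored.  Analytes censored
    in every sample are listed separately and excluded from testing.
    A missing LOD raises, naming the analyte.
    """
    t = analytes.copy()
    if lod is not None:
        missing = sorted(set(t["analyte"]) - set(lod))
        if missing:
            raise ValueError(f"no limit of detection for analyte(s): {missing}")
        t["lod"] = t["analyte"].map(lod)
    elif "lod" not in t.columns:
        raise ValueError(
            f"no limit of detection for analyte(s): {sorted(t['analyte'].unique())}"
        )
    else:
        bad = sorted(t.loc[t["lod"].isna(), "analyte"].unique())
        if bad:
            raise ValueError(f"no limit of detection for analyte(s): {bad}")
    t["censored"] = t["value"] < t["lod"]
    frac = t.groupby("analyte")["censored"].mean()
    fully = sorted(frac[frac == 1.0].index.tolist())
    return CensorResult(
        table=t,
        fully_censored=fully,
        censored_fraction={k: float(v) for k, v in frac.items()},
    )


def compare_analytes(
    censored: CensorResult, alpha: float = ALPHA, group_col: str = "group"
) -> tuple[list[StatResult], dict]:
    """Group comparisons for every testable analyte.

    Fully censored analytes are skipped (reported in the below-LOD block);
    an analyte whose censoring leaves any group with fewer than 3 values is
    skipped with a reason.
    """
    results: list[StatResult] = []
    skipped: dict[str, str] = {}
    testable = censored.testable()
    for analyte, sub in testable.groupby("analyte", sort=False):
        groups = {
            str(g): s["value"].to_numpy() for g, s in sub.groupby(group_col, sort=False)
        }
        small = [g for g, v in groups.items() if len(v) < 3]
        if len(groups) < 2 or small:
            skipped[str(analyte)] = (
                f"insufficient non-censored values in group(s) {small}"
                if small
                else "fewer than two groups"
            )
            continue
        results.append(compare_group_values(groups, variable=str(analyte), alpha=alpha))
    report = censored.below_lod_report()
    report["skipped"] = skipped
    return results, report
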