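"""Per-cell statistical comparison layer.

Standard hypothesis-testing plumbing, routed the way the analysis reports
its group comparisons: D'Agostino–Pearson normality check per group; two
normal groups → Student's t test (paired or unpaired, Welch when variances
differ); otherwise Mann-Whitney U (Wilcoxon when paired).  More than two
groups → one-way ANOVA with Holm-adjusted pairwise t tests, or
Kruskal-Wallis with Dunn's post hoc when any group is non-normal.
Distribution-level metrics (e.g. per-track s_mss distributions) use the
two-sample Kolmogorov-Smirnov test.  Every result records the route taken.

All inputs are per-cell values (or per-ROI values); trajectories are never
pooled across cells into a single test sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

NORMALITY_ALPHA = 0.05
#: D'Agostino–Pearson needs at least 8 observations; smaller groups are
#: routed non-parametric with the reason recorded.
NORMALITY_MIN_N = 8


@dataclass
class TestDescriptor:
    name: str
    paired: bool
    normal: bool
    equal_var: bool | None
    n_groups: int
    route: str  # human-readable routing note


@dataclass
class ComparisonResult:
    metric: str
    groups: list
    test: str
    statistic: float
    p_value: float
    adjusted: bool
    normality: str
    n_per_group: list
    posthoc: pd.DataFrame | None = None


def _group_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    if len(x) < NORMALITY_MIN_N:
        return False
    return sps.normaltest(x).pvalue > alpha


def select_test(groups: list, paired: bool = False, alpha: float = NORMALITY_ALPHA) -> TestDescriptor | None:
    """Choose the test for the given per-cell value groups.

    Returns None (no-test signal) when any group has fewer than 3 values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        return None
    normal = all(_group_normal(g, alpha) for g in groups)
    if len(groups) == 2:
        if normal:
            if paired:
                return TestDescriptor("paired t-test", True, True, None, 2, "normal, paired")
            lev = sps.levene(*groups).pvalue
            equal = lev > alpha
            name = "t-test" if equal else "Welch t-test"
            return TestDescriptor(name, False, True, equal, 2, f"normal, levene p={lev:.3g}")
        name = "Wilcoxon signed-rank" if paired else "Mann-Whitney U"
        return TestDescriptor(name, paired, False, None, 2, "non-normal")
    if normal:
        return TestDescriptor("one-way ANOVA + Holm pairwise t", False, True, None, len(groups), "normal, multi-group")
    return TestDescriptor("Kruskal-Wallis + Dunn", False, False, None, len(groups), "non-normal, multi-group")


def dunn_posthoc(groups: list, labels: list | None = None, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's post hoc rank comparison after Kruskal-Wallis.

    Pairwise z statistics on mean ranks with tie correction; p values
    adjusted (Holm by default).  Adjusted p values are never smaller than
    the unadjusted ones.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    splits = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        ni, nj = len(groups[i]), len(groups[j])
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_unadjusted": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_unadjusted"], method=adjust)[1]
    return df


def run_test(groups: list, desc: TestDescriptor) -> ComparisonResult:
    """Execute a selected test; posthoc table attached for multi-group routes."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    posthoc = None
    adjusted = False
    if desc.n_groups == 2:
        a, b = groups
        if desc.name == "paired t-test":
            stat, p = sps.ttest_rel(a, b)
        elif desc.name == "t-test":
            stat, p = sps.ttest_ind(a, b, equal_var=True)
        elif desc.name == "Welch t-test":
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        elif desc.name == "Wilcoxon signed-rank":
            stat, p = sps.wilcoxon(a, b)
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    elif desc.normal:
        stat, p = sps.f_oneway(*groups)
        rows = []
        for i, j in combinations(range(len(groups)), 2):
            s, pu = sps.ttest_ind(groups[i], groups[j])
            rows.append({"group_a": i, "group_b": j, "t": s, "p_unadjusted": pu})
        posthoc = pd.DataFrame(rows)
        posthoc["p_adjusted"] = multipletests(posthoc["p_unadjusted"], method="holm")[1]
        adjusted = True
    else:
        stat, p = sps.kruskal(*groups)
        posthoc = dunn_posthoc(groups)
        adjusted = True
    return ComparisonResult(
        metric="",
        groups=[],
        test=desc.name,
        statistic=float(stat),
        p_value=float(p),
        adjusted=adjusted,
        normality="normal" if desc.normal else "non-normal",
        n_per_group=[len(g) for g in groups],
        posthoc=posthoc,
    )


def run_comparisons(
    datasets: dict,
    metrics: list,
    alpha: float = 0.05,
    paired: bool = False,
    distribution_metrics: tuple = ("s_mss",),
) -> list[ComparisonResult]:
    """Compare each metric across condition datasets.

    ``datasets`` maps condition label → {metric → per-cell value array}.
    Metrics named in ``distribution_metrics`` are treated as pooled
    distributions and compared with the two-sample Kolmogorov-Smirnov test
    (only defined for two conditions).  Others go through
    :func:`select_test`.
    """
    labels = list(datasets)
    if len(labels) < 2:
        raise ValueError("need at least two conditions")
    results = []
    for metric in metrics:
        for lab in labels:
            if metric not in datasets[lab]:
                raise KeyError(f"metric {metric!r} missing from condition {lab!r}")
        groups = [np.asarray(datasets[lab][metric], dtype=float) for lab in labels]
        if metric in distribution_metrics:
            if len(groups) != 2:
                raise ValueError("KS route is defined for exactly two conditions")
            stat, p = sps.ks_2samp(groups[0], groups[1])
            res = ComparisonResult(
                metric=metric,
                groups=labels,
                test="Kolmogorov-Smirnov",
                statistic=float(stat),
                p_value=float(p),
                adjusted=False,
                normality="n/a",
                n_per_group=[len(g) for g in groups],
            )
        else:
            desc = select_test(groups, paired=paired)
            if desc is None:
                res = ComparisonResult(
                    metric=metric,
                    groups=labels,
                    test="none (insufficient n)",
                    statistic=np.nan,
                    p_value=np.nan,
                    adjusted=False,
                    normality="n/a",
                    n_per_group=[len(g) for g in groups],
                )
            else:
                res = run_test(groups, desc)
                res.metric = metric
                res.groups = labels
        res.metric = metric
        results.append(res)
    return results


def comparison_table(results: list) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric,
            "groups": "|".join(str(g) for g in r.groups),
            "test": r.test,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "significant_0.05": bool(r.p_value < 0.05) if np.isfinite(r.p_value) else False,
            "normality": r.normality,
            "n_per_group": "|".join(str(n) for n in r.n_per_group),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def text_summary(results: list) -> str:
    lines = []
    for r in results:
        n = ", ".join(str(v) for v in r.n_per_group)
        lines.append(
            f"{r.metric}: {r.test} (n = {n}; {r.normality}) "
            f"statistic = {r.statistic:.4g}, p = {r.p_value:.4g}"
            + (" *" if np.isfinite(r.p_value) and r.p_value < 0.05 else "")
        )
    return "\n".join(lines)
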