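"""Group comparisons and correlation reporting for metric tables.

Metric tables are tidy DataFrames with columns ``animal, group, day, metric,
value`` (one value per animal/day/metric).  Group pairs within one (metric,
day) family are compared with Welch's unpaired t-test and Holm-Sidak
adjustment across the family; associations are reported as Spearman rank
coefficients (r) or Pearson r-squared, the two conventions used for
longitudinal lung-function panels and cross-modality heatmaps respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

METRIC_COLUMNS = ["animal", "group", "day", "metric", "value"]


def validate_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table lacks columns {missing}")
    dup = table.duplicated(subset=["animal", "day", "metric"])
    if dup.any():
        raise ValueError("metric table has duplicate (animal, day, metric) cells")
    return table


@dataclass
class ComparisonResult:
    """One Welch comparison within a (metric, day) family."""

    group_a: str
    group_b: str
    day: int
    metric: str
    t: float
    p_raw: float
    p_adjusted: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    significant: bool

    def __post_init__(self):
        if not (np.isnan(self.p_adjusted) or self.p_adjusted >= self.p_raw - 1e-12):
            raise ValueError("adjusted p must be >= raw p")


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unpaired two-sided t-test; (nan, nan) when both groups are constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.nan, np.nan  # undefined t, flagged by caller
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def holm_sidak(p_raw) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (monotone in the raw p)."""
    p = np.asarray(p_raw, dtype=float)
    if len(p) == 1:
        return p.copy()
    ok = ~np.isnan(p)
    adj = np.full(len(p), np.nan)
    if ok.any():
        with np.errstate(divide="ignore"):  # log1p(-1) for p == 1 internally
            adj[ok] = multipletests(p[ok], method="holm-sidak")[1]
    return adj


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    day: int,
    pairs: list[tuple[str, str]],
    alpha: float = 0.05,
    pooled: bool = False,
) -> list[ComparisonResult]:
    """Welch t-tests for the given group pairs at one (metric, day) cell.

    Holm-Sidak adjustment is applied across exactly the pairs tested here
    (the per-panel starring convention).  ``pooled=True`` switches to the
    classical pooled-variance t-test.
    """
    validate_metric_table(table)
    sub = table[(table.metric == metric) & (table.day == day)]
    results, praw = [], []
    for ga, gb in pairs:
        a = sub[sub.group == ga].value.to_numpy()
        b = sub[sub.group == gb].value.to_numpy()
        if pooled:
            t, p = (float(v) for v in sps.ttest_ind(a, b, equal_var=True))
            if np.std(a) == 0 and np.std(b) == 0:
                t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.nan, np.nan)
        else:
            t, p = welch_t(a, b)
        praw.append(p)
        results.append((ga, gb, a, b, t, p))
    padj = holm_sidak(praw)
    out = []
    for (ga, gb, a, b, t, p), q in zip(results, padj):
        out.append(ComparisonResult(
            group_a=ga, group_b=gb, day=day, metric=metric,
            t=t, p_raw=p, p_adjusted=float(q),
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b),
            significant=bool(q < alpha) if not np.isnan(q) else False,
        ))
    return out


@dataclass
class CorrelationEntry:
    metric_x: str
    metric_y: str
    group: str
    method: str  # "spearman_r" or "pearson_r2"
    value: float
    n: int


def correlate(x, y, method: str = "spearman") -> tuple[float, int]:
    """Spearman r (average-rank ties) or Pearson r^2 of paired observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "spearman":
        r, _ = sps.spearmanr(x, y)
        return float(r), len(x)
    if method == "pearson":
        r, _ = sps.pearsonr(x, y)
        return float(r) ** 2, len(x)
    raise ValueError(f"unknown method {method!r}")


def correlate_metrics(
    table: pd.DataFrame,
    metric_x: str,
    metric_y: str,
    method: str = "spearman",
    by_group: bool = True,
    days=None,
) -> list[CorrelationEntry]:
    """Pair two metrics on (animal, day) and correlate, per group or pooled."""
    validate_metric_table(table)
    sub = table[table.metric.isin([metric_x, metric_y])]
    if days is not None:
        sub = sub[sub.day.isin(days)]
    wide = sub.pivot_table(index=["animal", "group", "day"], columns="metric",
                           values="value").reset_index()
    wide = wide.dropna(subset=[metric_x, metric_y])
    groups = sorted(wide.group.unique()) if by_group else ["all"]
    out = []
    for g in groups:
        w = wide if g == "all" else wide[wide.group == g]
        val, n = correlate(w[metric_x], w[metric_y], method=method)
        label = "spearman_r" if method == "spearman" else "pearson_r2"
        out.append(CorrelationEntry(metric_x=metric_x, metric_y=metric_y,
                                    group=g, method=label, value=val, n=n))
    return out


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def correlations_frame(entries: list[CorrelationEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD and n per (metric, group, day)."""
    validate_metric_table(table)
    return (table.groupby(["metric", "group", "day"])
            .value.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
            .reset_index())


DEFAULT_PAIRS = [("healthy", "vehicle"), ("healthy", "nintedanib"),
                 ("vehicle", "nintedanib")]


def cohort_report(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    correlation_pairs: list[tuple[str, str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Full statistical report over a study metric table.

    Returns {"summary", "comparisons", "correlations", "missing"} frames:
    longitudinal group summaries, all pairwise Welch comparisons per
    (metric, day) with Holm-Sidak stars, Spearman correlation entries for
    the requested metric pairs, and any missing (animal, day, metric) cells
    (reported, never imputed).
    """
    validate_metric_table(table)
    pairs = pairs or [p for p in DEFAULT_PAIRS
                      if set(p) <= set(table.group.unique())]
    comp = []
    for metric in sorted(table.metric.unique()):
        for day in sorted(table[table.metric == metric].day.unique()):
            cell = table[(table.metric == metric) & (table.day == day)]
            testable = [p for p in pairs
                        if all((cell.group == g).sum() >= 2 for g in p)]
            if testable:
                comp.extend(compare_groups(table, metric, day, testable))
    corr = []
    if correlation_pairs:
        for mx, my in correlation_pairs:
            try:
                corr.extend(correlate_metrics(table, mx, my))
            except ValueError:
                pass  # too few paired cells for this metric pair
    # missing-cell audit: every animal should have every metric on the days
    # that metric was measured at all
    missing = []
    for metric in sorted(table.metric.unique()):
        tm = table[table.metric == metric]
        animals = table[["animal", "group"]].drop_duplicates()
        for day in sorted(tm.day.unique()):
            have = set(tm[tm.day == day].animal)
            for _, row in animals.iterrows():
                if row.animal not in have:
                    missing.append({"animal": row.animal, "group": row.group,
                                    "day": day, "metric": metric})
    return {
        "summary": group_summary(table),
        "comparisons": comparisons_frame(comp),
        "correlations": correlations_frame(corr),
        "missing": pd.DataFrame(missing,
                                columns=["animal", "group", "day", "metric"]),
    }
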