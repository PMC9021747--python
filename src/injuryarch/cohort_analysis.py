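"""Cohort-level descriptive machinery.

Cortex filtering, clinical-AKI labelling of "no major abnormalities"
biopsies, sliding-window moving averages for trend plots, per-group
clinical summaries, contingency tables, and two-group tests.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MovingAverageSeries",
    "filter_low_cortex",
    "clinical_aki_label",
    "moving_average",
    "standardized_trend",
    "group_summary",
    "contingency",
    "compare_groups",
]

log = logging.getLogger(__name__)

#: biopsies at or before this day post-transplant count as early ("<=6 weeks")
EARLY_DAYS = 42


@dataclasses.dataclass
class MovingAverageSeries:
    """Sliding-window means of (x, y), window advanced one biopsy at a time."""

    window: int
    x_means: np.ndarray
    y_means: np.ndarray
    order_var: str = "x"

    def __len__(self) -> int:
        return len(self.x_means)


def filter_low_cortex(
    clinical: pd.DataFrame, threshold_pct: float = 10.0
) -> tuple[pd.DataFrame, int]:
    """Drop biopsies whose estimated cortex content is below threshold.

    Rows with a missing estimate are retained (and logged).  Returns
    the retained table and the removal count.
    """
    est = clinical["pct_cortex_estimate"]
    missing = est.isna()
    if missing.any():
        log.info("%d biopsies lack a cortex estimate; retained", int(missing.sum()))
    drop = est.notna() & (est < threshold_pct)
    return clinical.loc[~drop].reset_index(drop=True), int(drop.sum())


def clinical_aki_label(histology_dx: str, days_post_transplant: int) -> str:
    """Relabel histologically unremarkable biopsies by timing.

    "no major abnormalities" becomes "clinical AKI" at <= 42 days (6
    weeks, boundary included) and "normal" later; any other diagnosis
    is returned unchanged.
    """
    if histology_dx == "no major abnormalities":
        return "clinical AKI" if days_post_transplant <= EARLY_DAYS else "normal"
    return histology_dx


def moving_average(
    x: Sequence[float], y: Sequence[float], w: int = 400, order_var: str = "x"
) -> MovingAverageSeries:
    """Means of x and y over windows of w biopsies ordered by ascending x.

    The joint sort is stable, so ties in x keep input order.  The
    window advances one biopsy at a time, giving n - w + 1 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if w < 1 or w > len(x):
        raise ValueError(f"window w={w} must satisfy 1 <= w <= n={len(x)}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    kernel = np.full(w, 1.0 / w)
    x_means = np.convolve(xs, kernel, mode="valid")
    y_means = np.convolve(ys, kernel, mode="valid")
    return MovingAverageSeries(w, x_means, y_means, order_var)


def standardized_trend(
    A: pd.DataFrame, order_var: Sequence[float], w: int = 400
) -> dict[str, MovingAverageSeries]:
    """One moving-average series per archetype-score column, in SD units.

    Each column is z-scored across the whole cohort before windowing,
    so every series has overall mean 0 and the y-axis reads in standard
    deviations.
    """
    out: dict[str, MovingAverageSeries] = {}
    x = np.asarray(order_var, dtype=float)
    for col in A.columns:
        y = A[col].to_numpy(dtype=float)
        sd = y.std(ddof=1)
        z = (y - y.mean()) / (sd if sd > 0 else 1.0)
        out[str(col)] = moving_average(x, z, w=w, order_var="order")
    return out


def _pct(mask: pd.Series) -> float:
    denom = mask.notna().sum()
    return float("nan") if denom == 0 else 100.0 * float(mask.sum()) / float(denom)


def group_summary(
    assignments: pd.DataFrame,
    clinical: pd.DataFrame,
    rejection_filter: str = "all",
) -> pd.DataFrame:
    """Per-group clinical summary in the style of the cohort tables.

    ``assignments`` needs ``sample_id`` and a ``label`` (or
    ``archetype_index``) column.  ``rejection_filter`` of
    ``"no-rejection-only"`` restricts to biopsies whose
    ``rejection_group`` is "no-rejection".  Missing covariates are
    excluded per statistic, with denominators reported.
    """
    if rejection_filter not in ("all", "no-rejection-only"):
        raise ValueError(f"unknown rejection_filter {rejection_filter!r}")
    key = "label" if "label" in assignments.columns else "archetype_index"
    merged = clinical.merge(
        assignments[["sample_id", key]], on="sample_id", how="inner"
    )
    if rejection_filter == "no-rejection-only":
        merged = merged[merged["rejection_group"] == "no-rejection"]

    rows = []
    for group, sub in merged.groupby(key, observed=True, sort=True):
        days = sub["days_post_transplant"].astype(float)
        age = sub["donor_age"].astype(float)
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "median_days_post_transplant": days.median(),
                "mean_days_post_transplant": days.mean(),
                "mean_egfr": sub["egfr"].astype(float).mean(),
                "n_egfr": int(sub["egfr"].notna().sum()),
                "mean_donor_age": age.mean(),
                "median_donor_age": age.median(),
                "n_donor_age": int(age.notna().sum()),
                "pct_donor_age_over_50": _pct(age > 50),
                "pct_deceased_donor": _pct(sub["deceased_donor"]),
                "n_deceased_donor": int(sub["deceased_donor"].notna().sum()),
                "pct_dgf": _pct(sub["dgf"]),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    return out


def contingency(
    assignments: pd.DataFrame,
    categories: pd.Series | Sequence,
    group_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and column percentages of a categorical variable by group.

    Returns ``(counts, column_pct)``; counts carry row/column margins
    under the label "Total".
    """
    key = group_col or ("label" if "label" in assignments.columns else "archetype_index")
    groups = assignments[key]
    cats = pd.Series(list(categories), index=groups.index)
    counts = pd.crosstab(cats, groups)
    pct = 100.0 * counts / counts.sum(axis=0)
    counts_m = counts.copy()
    counts_m.loc["Total"] = counts.sum(axis=0)
    counts_m["Total"] = counts_m.sum(axis=1)
    return counts_m, pct


def _fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher p by hypergeometric tail summation."""
    from math import comb

    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def compare_groups(values_or_table, g1=None, g2=None, test: str = "welch_t"):
    """Two-group comparison; returns ``(statistic, two_sided_p)``.

    ``welch_t`` and ``wilcoxon`` (rank-sum) take either two value
    sequences or ``(values, groups, g1, g2)``-style inputs via a tidy
    DataFrame.  ``fisher_exact`` takes a 2x2 nonnegative integer table
    and uses the hypergeometric tail-sum definition.  The rank-sum form
    is used for "wilcoxon" because the compared groups are independent
    and of unequal size.
    """
    if test == "fisher_exact":
        table = np.asarray(values_or_table, dtype=int)
        if table.shape != (2, 2) or (table < 0).any():
            raise ValueError("fisher_exact requires a 2x2 nonnegative integer table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            warnings.warn("degenerate 2x2 table with an empty margin; p = 1")
            return 0.0, 1.0
        odds, _ = stats.fisher_exact(table)
        return float(odds), _fisher_exact_2x2(table)

    if g2 is not None:
        # tidy form: DataFrame with "value"/"group" columns, g1/g2 group labels
        df = values_or_table
        a = df.loc[df["group"] == g1, "value"].to_numpy(dtype=float)
        b = df.loc[df["group"] == g2, "value"].to_numpy(dtype=float)
    else:
        a = np.asarray(values_or_table, dtype=float)
        b = np.asarray(g1, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if test == "welch_t":
        if np.array_equal(np.sort(a), np.sort(b)) and a.std(ddof=1) == 0 == b.std(ddof=1):
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
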