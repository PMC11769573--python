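"""Summary statistics, RAP state classification, and subgroup comparisons.

RAP partitions into three clinical states: impaired compensatory reserve
(RAP in [0.4, 1]), intact reserve (RAP in (0, 0.4)), and exhausted reserve
(RAP in [-1, 0]).  Subgroup comparisons use the Mann-Whitney U test for two
groups (these signals are not normally distributed) and one-way ANOVA for
more than two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import IndexSeries, InvalidParameterError


@dataclass
class SummaryStats:
    count: int
    mean: float
    sd: float
    min: float
    q25: float
    median: float
    q75: float
    max: float


def summarize(series: IndexSeries | np.ndarray) -> SummaryStats:
    """Count, mean, sample SD, min, quartiles and max over non-missing values."""
    values = series.dropna() if isinstance(series, IndexSeries) else np.asarray(series, float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise InvalidParameterError("series has no non-missing values")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return SummaryStats(
        count=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        min=float(values.min()),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        max=float(values.max()),
    )


@dataclass
class RapStateRanges:
    """Threshold ranges partitioning [-1, 1] into the three RAP states.

    Boundary assignment: exactly 0.4 counts as impaired, exactly 0 as
    exhausted, so the three ranges are [-1, 0], (0, 0.4) and [0.4, 1].
    """

    impaired_lo: float = 0.4
    exhausted_hi: float = 0.0

    def classify(self, values: np.ndarray) -> dict[str, np.ndarray]:
        v = np.asarray(values, float)
        ok = ~np.isnan(v)
        return {
            "impaired": ok & (v >= self.impaired_lo),
            "intact": ok & (v > self.exhausted_hi) & (v < self.impaired_lo),
            "exhausted": ok & (v <= self.exhausted_hi),
        }


def time_in_ranges(
    rap: IndexSeries | np.ndarray, ranges: RapStateRanges | None = None
) -> dict[str, float]:
    """Percentage of non-missing time spent in each RAP state; sums to 100."""
    ranges = ranges or RapStateRanges()
    values = rap.values if isinstance(rap, IndexSeries) else np.asarray(rap, float)
    masks = ranges.classify(values)
    n_valid = (~np.isnan(values)).sum()
    if n_valid == 0:
        return {state: float("nan") for state in masks}
    return {state: float(100.0 * m.sum() / n_valid) for state, m in masks.items()}


@dataclass
class GroupComparison:
    grouping: str
    labels: list[str]
    summaries: dict[str, SummaryStats]
    test: str
    statistic: float
    p_value: float


def compare_groups(
    groups: Mapping[str, Sequence[float]], grouping: str = ""
) -> GroupComparison:
    """Formal comparison of >= 2 groups of values.

    Two groups: two-sided Mann-Whitney U (SciPy default tie correction and,
    for small samples without ties, the exact null).  More than two groups:
    one-way ANOVA.  Missing values are removed per group first.
    """
    cleaned: dict[str, np.ndarray] = {}
    for label, values in groups.items():
        v = np.asarray(values, float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise InvalidParameterError(
                f"group {label!r} has fewer than 2 non-missing values"
            )
        cleaned[str(label)] = v
    if len(cleaned) < 2:
        raise InvalidParameterError("at least 2 groups required")
    labels = list(cleaned)
    if len(cleaned) == 2:
        stat, p = stats.mannwhitneyu(
            cleaned[labels[0]], cleaned[labels[1]], alternative="two-sided"
        )
        test = "mann-whitney-u"
    else:
        stat, p = stats.f_oneway(*cleaned.values())
        test = "one-way-anova"
    return GroupComparison(
        grouping=grouping,
        labels=labels,
        summaries={lab: summarize(v) for lab, v in cleaned.items()},
        test=test,
        statistic=float(stat),
        p_value=float(p),
    )


def split_by_thresholds(
    values: np.ndarray,
    groupby: np.ndarray,
    lower: float,
    upper: float | None = None,
    labels: tuple[str, str] = ("low", "high"),
) -> dict[str, np.ndarray]:
    """Assign each sample of ``values`` to a group by its concurrent
    ``groupby`` value.

    With a single threshold, groups are ``groupby < lower`` vs
    ``groupby > lower``.  With dual thresholds (e.g. ICP below 20 vs above
    22 mmHg) samples falling in the dead zone [lower, upper] are excluded.
    """
    v = np.asarray(values, float)
    g = np.asarray(groupby, float)
    if v.shape != g.shape:
        raise InvalidParameterError("values and grouping variable must align")
    ok = ~(np.isnan(v) | np.isnan(g))
    hi_cut = lower if upper is None else upper
    return {
        labels[0]: v[ok & (g < lower)],
        labels[1]: v[ok & (g > hi_cut)],
    }
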