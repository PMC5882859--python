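"""Validation metrics against ground truth and the study's statistics.

Counting accuracy is the absolute relative error between automatic and
ground-truth counts; seed localization is validated as the mean
per-axis absolute deviation between matched seed/centroid pairs.
Group comparisons use the classic pooled-variance two-sample t-test
(two-tailed, equal variance) with significance stars at
p < 0.05 / 0.01 / 0.005 / 0.0005, and box-plot summaries report mean,
median, interquartile range, total range, and points beyond 1.5 x IQR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .seed3d import SeedSet
from .stacks_io import GroundTruth

__all__ = [
    "AccuracySummary",
    "CentroidDeviation",
    "GroupComparison",
    "BoxplotSummary",
    "counting_accuracy",
    "accuracy_summary",
    "centroid_deviation",
    "ttest_equal_var",
    "significance_stars",
    "summarize_boxplot",
]

DEFAULT_MATCH_RADIUS_PX = 5.0


def counting_accuracy(auto_count: int, truth_count: int) -> float:
    """Absolute percent counting error, |auto - truth| / truth x 100."""
    if truth_count <= 0:
        raise ValueError("truth count must be > 0")
    return abs(auto_count - truth_count) / truth_count * 100.0


@dataclass(frozen=True)
class AccuracySummary:
    """Per-region counting errors pooled into mean +/- SD."""

    per_region_error: tuple[float, ...]
    mean_error: float
    sd_error: float
    n_regions: int
    n_cells_total: int


def accuracy_summary(
    counts: Sequence[tuple[int, int]],
) -> AccuracySummary:
    """Summarize (auto, truth) count pairs across validation regions."""
    errors = [counting_accuracy(a, t) for a, t in counts]
    arr = np.asarray(errors, dtype=float)
    return AccuracySummary(
        per_region_error=tuple(errors),
        mean_error=float(arr.mean()),
        sd_error=float(arr.std(ddof=1)) if len(errors) > 1 else 0.0,
        n_regions=len(errors),
        n_cells_total=int(sum(t for _, t in counts)),
    )


@dataclass(frozen=True)
class CentroidDeviation:
    """Per-axis localization error of matched seeds, in pixels."""

    per_axis: tuple[float, float, float]  # mean |dz|, |dy|, |dx|
    n_matched: int
    n_unmatched_seeds: int
    n_unmatched_truth: int

    @property
    def max_axis(self) -> float:
        return max(self.per_axis)


def _as_positions(obj) -> np.ndarray:
    if isinstance(obj, SeedSet):
        return obj.positions()
    if isinstance(obj, GroundTruth):
        return obj.centroids
    return np.asarray(obj, dtype=float).reshape(-1, 3)


def centroid_deviation(
    seeds,
    truth,
    match_radius: float = DEFAULT_MATCH_RADIUS_PX,
) -> CentroidDeviation:
    """Greedy nearest-neighbour matching, then mean |deviation| per axis.

    Pairs are matched globally nearest-first within ``match_radius``
    (euclidean, pixels); each seed and each truth centroid is used at
    most once.  Raises if nothing matches.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    a = _as_positions(seeds)
    b = _as_positions(truth)
    if a.size == 0 or b.size == 0:
        raise ValueError("nothing to compare")
    diff = a[:, None, :] - b[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    dist = np.where(dist <= match_radius, dist, np.inf)
    pairs: list[tuple[int, int]] = []
    work = dist.copy()
    while np.isfinite(work).any():
        i, j = np.unravel_index(np.argmin(work), work.shape)
        pairs.append((int(i), int(j)))
        work[i, :] = np.inf
        work[:, j] = np.inf
    if not pairs:
        raise ValueError("nothing to compare: no matches within the radius")
    deltas = np.abs(np.array([a[i] - b[j] for i, j in pairs]))
    per_axis = tuple(float(v) for v in deltas.mean(axis=0))
    return CentroidDeviation(
        per_axis=per_axis,  # type: ignore[arg-type]
        n_matched=len(pairs),
        n_unmatched_seeds=a.shape[0] - len(pairs),
        n_unmatched_truth=b.shape[0] - len(pairs),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison by the pooled-variance Student's t-test."""

    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    t_statistic: float
    p_value: float
    stars: str


def significance_stars(p: float) -> str:
    """Stars at the study's thresholds: * 0.05, ** 0.01, *** 0.005, **** 0.0005."""
    if p < 0.0005:
        return "****"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ttest_equal_var(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Two-tailed equal-variance Student's t-test (pooled variance).

    ``t = (mean_a - mean_b) / sqrt(s_p^2 (1/n_a + 1/n_b))`` with
    ``df = n_a + n_b - 2``; the two-sided p-value comes from the t
    distribution.  Identical groups give ``t = 0, p = 1``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    dmean = a.mean() - b.mean()
    if sp2 <= 0:
        if dmean == 0:
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError("degenerate (zero) pooled variance with unequal means")
    else:
        t_stat = dmean / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = 2.0 * float(_scipy_stats.t.sf(abs(t_stat), df))
    return GroupComparison(
        group_a=tuple(float(v) for v in a),
        group_b=tuple(float(v) for v in b),
        t_statistic=float(t_stat),
        p_value=float(p),
        stars=significance_stars(p),
    )


@dataclass(frozen=True)
class BoxplotSummary:
    """Numbers behind the study-style box plot (whiskers = total range)."""

    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]  # beyond 1.5 x IQR from the quartiles

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def summarize_boxplot(values: Sequence[float]) -> BoxplotSummary:
    """Box-plot summary with linear-interpolation quartiles.

    Quartiles use numpy's linear interpolation (so e.g. Q1 of 1..9 is
    3); flagged points lie below ``Q1 - 1.5 IQR`` or above
    ``Q3 + 1.5 IQR``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)])
    return BoxplotSummary(
        mean=float(arr.mean()),
        median=med,
        q1=q1,
        q3=q3,
        whisker_low=float(arr.min()),
        whisker_high=float(arr.max()),
        outliers=outliers,
    )
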