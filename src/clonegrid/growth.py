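"""Clonal growth analysis on per-feature count tables.

Joins daily counts into per-feature time series, fits exponential growth
(log-linear least squares) to obtain rates and doubling times, classifies
clones into low / intermediate / high growth, compares groups with a
Student t-test, and computes limiting-dilution Poisson seeding statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTimeSeries",
    "GrowthFit",
    "GrowthClass",
    "SeedingPlan",
    "join_timepoints",
    "fit_exponential",
    "classify_growth",
    "compare_groups",
    "poisson_seeding",
    "growth_table",
]

NO_DOUBLING = math.inf  # sentinel doubling time for non-growing clones


@dataclass(frozen=True)
class FeatureTimeSeries:
    """Nuclei counts for one (well, grid_row, grid_col) across days."""

    well: int
    grid_row: int
    grid_col: int
    days: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.counts):
            raise ValueError("days and counts must be the same length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.well, self.grid_row, self.grid_col)

    @property
    def final_count(self) -> int:
        return self.counts[-1] if self.counts else 0


@dataclass(frozen=True)
class GrowthFit:
    """Result of a log-linear exponential growth fit.

    ``rate_per_day`` is the slope of ln(count) vs day; ``doubling_time_days``
    is ln(2)/rate for positive rates and +inf otherwise.  ``r_squared`` is
    None unless at least three points entered the fit.  Zero counts are
    excluded from the log fit; their days are recorded.
    """

    rate_per_day: float
    doubling_time_days: float
    r_squared: float | None
    n_points: int
    excluded_zero_days: tuple[int, ...] = ()
    ok: bool = True
    reason: str = ""

    @classmethod
    def failed(cls, reason: str, excluded: tuple[int, ...] = ()) -> "GrowthFit":
        return cls(
            rate_per_day=math.nan,
            doubling_time_days=math.nan,
            r_squared=None,
            n_points=0,
            excluded_zero_days=excluded,
            ok=False,
            reason=reason,
        )


@dataclass(frozen=True)
class GrowthClass:
    label: Literal["low", "intermediate", "high"]
    statistic: float
    low_max: float
    high_min: float


@dataclass(frozen=True)
class SeedingPlan:
    """Limiting-dilution Poisson seeding statistics.

    For seeding density λ (mean cells per feature), the probability that a
    feature holds 0 or 1 cell is (1 + λ)·e^(−λ) and the expected number of
    clonal (exactly-1-cell) features among ``n_features`` is n·λ·e^(−λ).
    """

    lam: float
    n_features: int
    p_zero_or_one: float
    expected_clonal_features: float


def join_timepoints(records: pd.DataFrame) -> list[FeatureTimeSeries]:
    """Join count records into one series per (well, grid_row, grid_col).

    Missing days are left as gaps, never interpolated.  Series are
    returned in key order, so the result is independent of record order.
    """
    if records.empty:
        return []
    required = {"well", "grid_row", "grid_col", "day", "nucleus_count"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    series = []
    grouped = records.sort_values(["well", "grid_row", "grid_col", "day"]).groupby(
        ["well", "grid_row", "grid_col"], sort=True
    )
    for (well, gr, gc), grp in grouped:
        series.append(
            FeatureTimeSeries(
                well=int(well),
                grid_row=int(gr),
                grid_col=int(gc),
                days=tuple(int(d) for d in grp["day"]),
                counts=tuple(int(c) for c in grp["nucleus_count"]),
            )
        )
    return series


def fit_exponential(series: FeatureTimeSeries, min_count: int = 1) -> GrowthFit:
    """Least-squares line on (day, ln count): slope = growth rate per day.

    Points with count below ``min_count`` (default 1, i.e. zeros) are
    excluded from the fit and recorded.  At least two usable points are
    required; otherwise a no-fit result explains why.
    """
    usable = [(d, c) for d, c in zip(series.days, series.counts) if c >= max(min_count, 1)]
    excluded = tuple(d for d, c in zip(series.days, series.counts) if c < max(min_count, 1))
    if len(usable) < 2:
        return GrowthFit.failed(
            f"need >= 2 points with count >= {min_count}, got {len(usable)}",
            excluded,
        )
    days = np.array([d for d, _ in usable], dtype=float)
    logs = np.log([c for _, c in usable])
    slope, intercept = np.polyfit(days, logs, 1)
    if abs(slope) < 1e-12:  # numerically flat
        slope = 0.0
    n = len(usable)
    if n >= 3:
        pred = slope * days + intercept
        ss_res = float(np.sum((logs - pred) ** 2))
        ss_tot = float(np.sum((logs - logs.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    else:
        r2 = None
    doubling = math.log(2.0) / slope if slope > 0 else NO_DOUBLING
    return GrowthFit(
        rate_per_day=float(slope),
        doubling_time_days=doubling,
        r_squared=r2,
        n_points=n,
        excluded_zero_days=excluded,
    )


def _tertile_thresholds(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(np.quantile(arr, 1 / 3)), float(np.quantile(arr, 2 / 3))


def classify_growth(
    statistics: Mapping[tuple[int, int, int], float],
    thresholds: tuple[float, float] | None = None,
) -> dict[tuple[int, int, int], GrowthClass]:
    """Three-way low / intermediate / high partition of a growth statistic.

    ``statistics`` maps feature keys to the chosen statistic (final-day
    count by default upstream; fitted rate also works).  ``thresholds`` is
    ``(low_max, high_min)``; values below ``low_max`` are low, values at or
    above ``high_min`` are high, the rest intermediate — boundary values go
    to the higher class.  Default thresholds are the tertiles of the input.
    """
    if not statistics:
        return {}
    defaulted = thresholds is None
    if thresholds is None:
        thresholds = _tertile_thresholds(list(statistics.values()))
    low_max, high_min = thresholds
    if not low_max < high_min:
        if defaulted:  # degenerate spread: everything is one class
            return {
                k: GrowthClass("intermediate", float(v), low_max, high_min)
                for k, v in statistics.items()
            }
        raise ValueError("thresholds must satisfy low_max < high_min")
    out = {}
    for key, value in statistics.items():
        if value >= high_min:
            label = "high"
        elif value >= low_max:
            label = "intermediate"
        else:
            label = "low"
        out[key] = GrowthClass(label, float(value), low_max, high_min)
    return out


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample two-tailed t-test (pooled-variance Student by default).

    Returns ``(t, p)``.  The degenerate zero-variance, equal-means case is
    mapped to ``(0, 1)`` by convention and logged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            logger.warning("both groups constant and equal; p = 1 by convention")
            return 0.0, 1.0
        logger.warning("both groups constant but unequal; p = 0 by convention")
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def poisson_seeding(lam: float, n_features: int) -> SeedingPlan:
    """Limiting-dilution statistics for Poisson seeding at density λ."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if n_features < 0:
        raise ValueError("n_features must be >= 0")
    p01 = (1.0 + lam) * math.exp(-lam)
    return SeedingPlan(
        lam=lam,
        n_features=n_features,
        p_zero_or_one=p01,
        expected_clonal_features=n_features * lam * math.exp(-lam),
    )


def growth_table(
    series_list: Sequence[FeatureTimeSeries],
    min_count: int = 1,
    thresholds: tuple[float, float] | None = None,
    statistic: Literal["final_count", "rate"] = "final_count",
) -> pd.DataFrame:
    """Fit and classify every series; one row per feature.

    Columns: well, grid_row, grid_col, rate_per_day, doubling_time_days,
    r_squared, n_points, final_count, growth_class.
    """
    fits = {s.key: fit_exponential(s, min_count=min_count) for s in series_list}
    stats_map: dict[tuple[int, int, int], float] = {}
    for s in series_list:
        if statistic == "final_count":
            stats_map[s.key] = float(s.final_count)
        else:
            f = fits[s.key]
            stats_map[s.key] = f.rate_per_day if f.ok else 0.0
    classes = classify_growth(stats_map, thresholds)
    rows = []
    for s in series_list:
        f = fits[s.key]
        cls = classes.get(s.key)
        rows.append(
            {
                "well": s.well,
                "grid_row": s.grid_row,
                "grid_col": s.grid_col,
                "rate_per_day": f.rate_per_day,
                "doubling_time_days": f.doubling_time_days,
                "r_squared": np.nan if f.r_squared is None else f.r_squared,
                "n_points": f.n_points,
                "final_count": s.final_count,
                "growth_class": cls.label if cls is not None else "",
            }
        )
    return pd.DataFrame(rows)
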