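"""Weekly category proportions, linear time trends, and RSV normalization.

The analysis model: classified query volume is aggregated into consecutive
7-day blocks anchored at the study start date; for each week and category
the volume-weighted proportion of queries carrying that category is
computed; each category's weekly proportion series (in percent) is then
regressed on week number by ordinary least squares, reported as
(beta, intercept, R^2, df = n - 2, two-sided p).

Relative search volume (RSV) rescales one or more count series jointly to a
0-100 scale where 100 is the global peak across all series, mirroring how
public search-trend tools report volumes.
"""

from __future__ import annotations

import datetime as dt
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classifier import DegenerateInputError
from .records import Category, ClassifiedQuery

__all__ = [
    "WeeklyCategoryShares",
    "TrendResult",
    "RSVSeries",
    "weekly_shares",
    "fit_trend",
    "rsv_normalize",
    "topk_volume_share",
    "share_ratio_series",
]


@dataclass(frozen=True, slots=True)
class WeeklyCategoryShares:
    """Volume-weighted category proportions for one 7-day block.

    ``shares`` maps each category to the fraction (in [0, 1]) of the week's
    query volume assigned that category.  Because queries are multi-label,
    the four specific-category shares may overlap; ``general_other`` plus
    the share of queries with at least one specific category equals 1.
    ``pharmacy_share`` is the fraction naming a specific pharmacy (a subset
    of availability, so pharmacy_share <= shares[AVAILABILITY]).
    """

    week_index: int
    week_start: dt.date
    total_volume: int
    shares: Mapping[Category, float]
    pharmacy_share: float


@dataclass(frozen=True, slots=True)
class TrendResult:
    """OLS fit of a proportion series on week (or day) index.

    When the input series is in percent, ``beta`` is percentage points per
    time step.  ``degenerate`` flags a constant response, for which the
    slope is 0 by convention and R^2 is reported as 0.
    """

    beta: float
    intercept: float
    r_squared: float
    df: int
    p_value: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True, slots=True)
class RSVSeries:
    """A relative-search-volume series on the 0-100 percentage scale."""

    label: str
    timestamps: tuple[dt.date, ...]
    values: tuple[float, ...]


def weekly_shares(
    classified: Iterable[ClassifiedQuery],
    window: tuple[dt.date, dt.date],
) -> list[WeeklyCategoryShares]:
    """Aggregate classified queries into weekly volume-weighted shares.

    Weeks are consecutive 7-day blocks starting at the window start; a
    trailing block shorter than 7 days is dropped.  Every record must fall
    inside the window.  A retained week with zero total volume raises
    :class:`DegenerateInputError` (a proportion is undefined there).
    """
    start, end = window
    if end < start:
        raise ValueError(f"empty study window: {start}..{end}")
    n_days = (end - start).days + 1
    n_weeks = n_days // 7
    if n_weeks == 0:
        raise DegenerateInputError(
            f"window {start}..{end} contains no full 7-day week"
        )

    volume = np.zeros(n_weeks, dtype=np.int64)
    cat_volume = {cat: np.zeros(n_weeks, dtype=np.int64) for cat in Category}
    pharmacy_volume = np.zeros(n_weeks, dtype=np.int64)

    for cq in classified:
        day = (cq.record.date - start).days
        if day < 0 or day >= n_days:
            raise ValueError(
                f"record date {cq.record.date} outside window {start}..{end}"
            )
        week = day // 7
        if week >= n_weeks:  # trailing partial week
            continue
        c = cq.record.count
        volume[week] += c
        for cat in cq.categories:
            cat_volume[cat][week] += c
        if cq.pharmacy:
            pharmacy_volume[week] += c

    if (volume == 0).any():
        empty = [int(w) for w in np.nonzero(volume == 0)[0]]
        raise DegenerateInputError(f"zero query volume in week(s) {empty}")

    out = []
    for w in range(n_weeks):
        out.append(
            WeeklyCategoryShares(
                week_index=w,
                week_start=start + dt.timedelta(days=7 * w),
                total_volume=int(volume[w]),
                shares={
                    cat: float(cat_volume[cat][w] / volume[w]) for cat in Category
                },
                pharmacy_share=float(pharmacy_volume[w] / volume[w]),
            )
        )
    return out


def fit_trend(series: Sequence[tuple[float, float]]) -> TrendResult:
    """Ordinary least squares of a proportion series on its time index.

    ``series`` is an ordered sequence of (time_index, value) pairs with at
    least 3 points.  Returns slope, intercept, coefficient of
    determination, residual degrees of freedom (n - 2) and the two-sided
    t-test p-value for the slope.  A constant response is degenerate by
    convention: beta = 0, R^2 = 0, p = 1.  A constant predictor is an
    error (no trend is identifiable).
    """
    t = np.asarray([p[0] for p in series], dtype=float)
    y = np.asarray([p[1] for p in series], dtype=float)
    n = t.size
    if n < 3:
        raise ValueError(f"need >= 3 points for a trend fit, got {n}")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in trend series")
    if np.ptp(t) == 0:
        raise ValueError("constant time index: trend is not identifiable")
    if np.ptp(y) == 0:
        return TrendResult(
            beta=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            df=n - 2,
            p_value=1.0,
            n_points=n,
            degenerate=True,
        )
    res = stats.linregress(t, y)
    return TrendResult(
        beta=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        df=n - 2,
        p_value=float(res.pvalue),
        n_points=n,
    )


def rsv_normalize(
    series_set: Sequence[tuple[str, Sequence[dt.date], Sequence[float]]],
    round_to_int: bool = False,
) -> list[RSVSeries]:
    """Jointly normalize one or more count series to the 0-100 RSV scale.

    All series share a single global maximum, which maps to 100; searching
    for several terms "simultaneously" in this way makes their relative
    volumes comparable.  A single series is normalized against its own
    peak.  All-zero input raises :class:`DegenerateInputError`.

    ``round_to_int`` mimics the integer output of public search-trend
    tools; by default full float precision is kept.
    """
    if not series_set:
        raise ValueError("series_set must contain at least one series")
    arrays = []
    for label, ts, values in series_set:
        arr = np.asarray(values, dtype=float)
        if (arr < 0).any():
            raise ValueError(f"negative counts in series {label!r}")
        if len(ts) != arr.size:
            raise ValueError(f"timestamp/value length mismatch in {label!r}")
        arrays.append(arr)
    peak = max(arr.max(initial=0.0) for arr in arrays)
    if peak <= 0:
        raise DegenerateInputError("all series are identically zero")
    out = []
    for (label, ts, _), arr in zip(series_set, arrays):
        scaled = arr * (100.0 / peak)
        if round_to_int:
            scaled = np.rint(scaled)
        out.append(
            RSVSeries(
                label=label,
                timestamps=tuple(ts),
                values=tuple(float(v) for v in scaled),
            )
        )
    return out


def topk_volume_share(freq: Mapping[str, int], k: int) -> float:
    """Fraction of total query volume carried by the k most common queries.

    Quantifies the heavy-tailed concentration of query logs: a small
    number of distinct queries accounts for a large share of total volume.
    """
    if not freq:
        raise ValueError("empty frequency table")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = np.sort(np.asarray(list(freq.values()), dtype=float))[::-1]
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("zero total volume")
    return float(counts[:k].sum() / total)


def share_ratio_series(
    numerator: Sequence[float], denominator: Sequence[float]
) -> np.ndarray:
    """Pointwise fraction numerator/denominator for two aligned count series.

    Used to track e.g. the fraction of all covid-related queries that are
    vaccine-related, day by day.  Requires 0 <= numerator <= denominator
    pointwise and a strictly positive denominator.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("series length mismatch")
    if (den <= 0).any():
        raise DegenerateInputError("zero or negative denominator volume")
    if (num < 0).any() or (num > den).any():
        raise ValueError("numerator must satisfy 0 <= num <= den pointwise")
    return num / den


def shares_to_percent_series(
    weeks: Sequence[WeeklyCategoryShares], category: Category | None = None
) -> list[tuple[float, float]]:
    """Extract a (week_index, share-in-percent) series for trend fitting.

    ``category=None`` selects the pharmacy subcategory share.
    """
    if category is None:
        return [(float(w.week_index), 100.0 * w.pharmacy_share) for w in weeks]
    return [(float(w.week_index), 100.0 * w.shares[category]) for w in weeks]


def fit_all_trends(
    weeks: Sequence[WeeklyCategoryShares],
) -> dict[str, TrendResult]:
    """Fit per-category weekly trends (percent scale), plus pharmacy."""
    out = {
        cat.value: fit_trend(shares_to_percent_series(weeks, cat))
        for cat in Category
    }
    out["pharmacy"] = fit_trend(shares_to_percent_series(weeks, None))
    return out
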