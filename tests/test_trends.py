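"""Weekly shares, OLS trend fits, RSV normalization, volume concentration."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vaxquery import (
    Category,
    ClassifiedQuery,
    QueryRecord,
    fit_trend,
    rsv_normalize,
    share_ratio_series,
    topk_volume_share,
    weekly_shares,
)
from vaxquery.classifier import DegenerateInputError

D0 = dt.date(2021, 1, 1)


def _cq(day, text, count, cats, pharmacy=False):
    return ClassifiedQuery(
        record=QueryRecord(D0 + dt.timedelta(days=day), text, count),
        categories=frozenset(cats),
        pharmacy=pharmacy,
    )


# ----------------------------------------------------------------- weekly


def test_weekly_shares_single_week_ratios():
    classified = [
        _cq(0, "ny covid vaccine", 60, {Category.AVAILABILITY}),
        _cq(2, "pfizer covid vaccine", 10, {Category.MANUFACTURER}),
        _cq(5, "covid vaccine", 30, {Category.GENERAL_OTHER}),
    ]
    weeks = weekly_shares(classified, (D0, D0 + dt.timedelta(days=6)))
    assert len(weeks) == 1
    w = weeks[0]
    assert w.total_volume == 100
    assert w.shares[Category.AVAILABILITY] == pytest.approx(0.60)
    assert w.shares[Category.MANUFACTURER] == pytest.approx(0.10)
    assert w.shares[Category.GENERAL_OTHER] == pytest.approx(0.30)
    assert w.pharmacy_share == 0.0


def test_weekly_shares_multilabel_counted_in_each_category():
    """A query in two categories contributes its full volume to both."""
    classified = [
        _cq(0, "pfizer covid vaccine cvs", 10,
            {Category.AVAILABILITY, Category.MANUFACTURER}, pharmacy=True),
    ]
    w = weekly_shares(classified, (D0, D0 + dt.timedelta(days=6)))[0]
    assert w.shares[Category.AVAILABILITY] == 1.0
    assert w.shares[Category.MANUFACTURER] == 1.0
    assert w.pharmacy_share == 1.0


def test_weekly_shares_window_partition():
    """A 75-day window yields 10 full weeks; 5 trailing days are dropped."""
    window = (dt.date(2021, 1, 1), dt.date(2021, 3, 16))
    assert (window[1] - window[0]).days + 1 == 75
    classified = [
        _cq(d, "covid vaccine", 1, {Category.GENERAL_OTHER}) for d in range(75)
    ]
    weeks = weekly_shares(classified, window)
    assert len(weeks) == 10
    assert [w.week_index for w in weeks] == list(range(10))
    assert weeks[0].week_start == dt.date(2021, 1, 1)
    assert weeks[9].week_start == dt.date(2021, 3, 5)
    # every retained record in exactly one week: retained volume = 70
    assert sum(w.total_volume for w in weeks) == 70


def test_weekly_shares_rejects_empty_week():
    classified = [
        _cq(0, "covid vaccine", 5, {Category.GENERAL_OTHER}),
        _cq(13, "covid vaccine", 5, {Category.GENERAL_OTHER}),
    ]
    with pytest.raises(DegenerateInputError, match="zero query volume"):
        weekly_shares(classified, (D0, D0 + dt.timedelta(days=20)))


def test_weekly_shares_rejects_out_of_window_record():
    classified = [_cq(10, "covid vaccine", 1, {Category.GENERAL_OTHER})]
    with pytest.raises(ValueError, match="outside window"):
        weekly_shares(classified, (D0, D0 + dt.timedelta(days=6)))


def test_weekly_shares_general_complement(small_classified, small_scenario):
    """General share equals 1 minus the share of queries with >= 1 specific
    category, week by week."""
    weeks = weekly_shares(small_classified, small_scenario.window)
    for w in weeks:
        specific_volume = sum(
            cq.record.count
            for cq in small_classified
            if cq.categories != frozenset({Category.GENERAL_OTHER})
            and 0 <= (cq.record.date - w.week_start).days < 7
        )
        assert w.shares[Category.GENERAL_OTHER] + specific_volume / w.total_volume \
            == pytest.approx(1.0)
        assert w.pharmacy_share <= w.shares[Category.AVAILABILITY] + 1e-12


# ------------------------------------------------------------------- OLS


def _closed_form_ols(t, y):
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    sxx = ((t - t.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    sxy = ((t - t.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * t.mean()
    r2 = sxy**2 / (sxx * syy)
    return slope, intercept, r2, n - 2


def test_fit_trend_perfect_line():
    res = fit_trend([(1, 1), (2, 2), (3, 3)])
    assert res.beta == pytest.approx(1.0)
    assert res.r_squared == pytest.approx(1.0)
    assert res.df == 1


def test_fit_trend_hand_checked_example():
    res = fit_trend(list(zip([1, 2, 3, 4, 5], [2, 4, 5, 4, 5])))
    assert res.beta == pytest.approx(0.6, abs=1e-12)
    assert res.intercept == pytest.approx(2.2, abs=1e-12)
    assert res.r_squared == pytest.approx(0.6, abs=1e-12)
    assert res.df == 3
    assert res.n_points == 5


def test_fit_trend_constant_response_is_degenerate():
    res = fit_trend([(0, 5.0), (1, 5.0), (2, 5.0)])
    assert res.degenerate
    assert res.beta == 0.0
    assert res.r_squared == 0.0
    assert res.p_value == 1.0


def test_fit_trend_constant_predictor_rejected():
    with pytest.raises(ValueError, match="constant time index"):
        fit_trend([(1, 1.0), (1, 2.0), (1, 3.0)])


def test_fit_trend_too_short_rejected():
    with pytest.raises(ValueError, match=">= 3 points"):
        fit_trend([(0, 1.0), (1, 2.0)])


def test_fit_trend_matches_closed_form_on_random_series():
    rng = np.random.default_rng(2021)
    for _ in range(100):
        n = rng.integers(5, 51)
        t = np.sort(rng.uniform(0, 20, n))
        y = rng.normal(0, 1, n) + rng.uniform(-2, 2) * t
        res = fit_trend(list(zip(t, y)))
        slope, intercept, r2, df = _closed_form_ols(t, y)
        assert res.beta == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        assert res.df == df


# ------------------------------------------------------------------- RSV


def test_rsv_peak_scaling():
    [s] = rsv_normalize([("a", [D0, D0, D0], [5, 10, 20])])
    assert s.values == (25.0, 50.0, 100.0)


def test_rsv_joint_normalization():
    a, b = rsv_normalize(
        [("a", [D0, D0], [10, 20]), ("b", [D0, D0], [40, 80])]
    )
    assert a.values == (12.5, 25.0)
    assert b.values == (50.0, 100.0)


def test_rsv_constant_series():
    [s] = rsv_normalize([("a", [D0, D0], [7, 7])])
    assert s.values == (100.0, 100.0)


def test_rsv_all_zero_rejected():
    with pytest.raises(DegenerateInputError):
        rsv_normalize([("a", [D0], [0.0])])


def test_rsv_rounding_mode():
    [s] = rsv_normalize([("a", [D0] * 3, [1, 2, 3])], round_to_int=True)
    assert s.values == (33.0, 67.0, 100.0)


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(0, 10**6), min_size=1, max_size=12),
        min_size=1,
        max_size=4,
    ).filter(lambda seqs: any(v > 0 for seq in seqs for v in seq)),
    st.floats(0.001, 1000.0),
)
def test_rsv_invariants(seqs, scale):
    """Joint peak equals 100 exactly at the global-max points, and RSV is
    invariant under rescaling all counts by any positive constant."""
    # pad to common length for timestamp bookkeeping
    series = [
        (f"s{i}", [D0] * len(seq), seq) for i, seq in enumerate(seqs)
    ]
    out = rsv_normalize(series)
    flat = [v for s in out for v in s.values]
    assert math.isclose(max(flat), 100.0, rel_tol=1e-12)
    assert all(v >= 0 for v in flat)
    global_max = max(v for seq in seqs for v in seq)
    for s, (_, _, seq) in zip(out, series):
        for v, raw in zip(s.values, seq):
            assert (raw == global_max) == math.isclose(v, 100.0, rel_tol=1e-12)
    scaled = rsv_normalize(
        [(lbl, ts, [v * scale for v in seq]) for lbl, ts, seq in series]
    )
    for s1, s2 in zip(out, scaled):
        for v1, v2 in zip(s1.values, s2.values):
            assert math.isclose(v1, v2, rel_tol=1e-9, abs_tol=1e-9)


# ----------------------------------------------------------- concentration


def test_topk_volume_share_examples():
    assert topk_volume_share({f"q{i}": 3 for i in range(10)}, 4) == pytest.approx(0.4)
    assert topk_volume_share({"a": 50, "b": 30, "c": 20}, 1) == pytest.approx(0.5)


def test_topk_volume_share_zipf_harmonic_oracle():
    n, k = 1000, 150
    freq = {f"q{i}": 0 for i in range(n)}
    weights = 1.0 / np.arange(1, n + 1)
    # exact expected counts (continuous), valid for the ratio identity
    for i in range(n):
        freq[f"q{i}"] = weights[i]
    h = np.cumsum(weights)
    assert topk_volume_share(freq, k) == pytest.approx(h[k - 1] / h[-1], abs=1e-12)


def test_topk_volume_share_monotone_in_k():
    rng = np.random.default_rng(5)
    freq = {f"q{i}": int(c) for i, c in enumerate(rng.integers(1, 100, 40))}
    shares = [topk_volume_share(freq, k) for k in range(1, 41)]
    assert all(b >= a for a, b in zip(shares, shares[1:]))
    assert shares[-1] == pytest.approx(1.0)


# ------------------------------------------------------------ share ratio


def test_share_ratio_examples():
    assert share_ratio_series([10, 50], [100, 100]) == pytest.approx([0.1, 0.5])
    assert share_ratio_series([3, 4], [3, 4]) == pytest.approx([1.0, 1.0])
    assert share_ratio_series([0, 0], [5, 9]) == pytest.approx([0.0, 0.0])


def test_share_ratio_zero_denominator_rejected():
    with pytest.raises(DegenerateInputError):
        share_ratio_series([0, 1], [5, 0])


def test_share_ratio_numerator_exceeding_denominator_rejected():
    with pytest.raises(ValueError, match="pointwise"):
        share_ratio_series([6], [5])
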