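"""Precision/recall scoring and specific-category coverage."""

import datetime as dt
import math
import random

import pytest

from vaxquery import (
    Category,
    ClassifiedQuery,
    GoldLabel,
    QueryRecord,
    precision_recall,
    specific_coverage,
)
from vaxquery.evaluation import JoinError
from vaxquery.lexicon import normalize_text

D0 = dt.date(2021, 2, 1)
SPECIFIC = [c for c in Category if c is not Category.GENERAL_OTHER]


def _pair(i, pred_cats, gold_cats, pred_ph=False, gold_ph=False, count=1):
    rec = QueryRecord(D0, f"q{i}", count)
    return (
        ClassifiedQuery(record=rec, categories=frozenset(pred_cats), pharmacy=pred_ph),
        GoldLabel(date=D0, text=f"q{i}", categories=frozenset(gold_cats), pharmacy=gold_ph),
    )


def _random_cats(rng):
    cats = set(rng.sample(SPECIFIC, k=rng.randint(0, 2)))
    return cats or {Category.GENERAL_OTHER}


def test_identity_gives_perfect_scores():
    pairs = [
        _pair(0, {Category.AVAILABILITY}, {Category.AVAILABILITY}, True, True),
        _pair(1, {Category.MANUFACTURER}, {Category.MANUFACTURER}),
        _pair(2, {Category.GENERAL_OTHER}, {Category.GENERAL_OTHER}),
    ]
    report = precision_recall([p for p, _ in pairs], [g for _, g in pairs])
    for cat in (Category.AVAILABILITY, Category.MANUFACTURER, Category.GENERAL_OTHER):
        assert report.categories[cat].precision == 1.0
        assert report.categories[cat].recall == 1.0
    assert report.pharmacy.precision == 1.0 and report.pharmacy.recall == 1.0
    assert report.n_queries == 3


def test_single_miss_recall():
    """10 gold myth queries, one missed, no false alarms: recall 0.9,
    precision 1.0."""
    pairs = [
        _pair(i, {Category.MYTHS_CONSPIRACY}, {Category.MYTHS_CONSPIRACY})
        for i in range(9)
    ]
    pairs.append(_pair(9, {Category.GENERAL_OTHER}, {Category.MYTHS_CONSPIRACY}))
    report = precision_recall([p for p, _ in pairs], [g for _, g in pairs])
    score = report.categories[Category.MYTHS_CONSPIRACY]
    assert score.recall == pytest.approx(0.9)
    assert score.precision == pytest.approx(1.0)
    assert (score.tp, score.fp, score.fn) == (9, 0, 1)


def test_counts_match_double_loop_oracle():
    """Confusion counts on a noisy random set equal an independent
    per-query, per-category tally."""
    rng = random.Random(13)
    for _ in range(100):
        n = rng.randint(1, 50)
        preds, golds = [], []

        # pharmacy requires availability (and excludes the fallback)
        def _with_avail(cats, pharmacy):
            if not pharmacy:
                return cats
            return (cats - {Category.GENERAL_OTHER}) | {Category.AVAILABILITY}

        for i in range(n):
            pred_ph = rng.random() < 0.2
            gold_ph = rng.random() < 0.2
            p, g = _pair(
                i,
                _with_avail(_random_cats(rng), pred_ph),
                _with_avail(_random_cats(rng), gold_ph),
                pred_ph=pred_ph,
                gold_ph=gold_ph,
            )
            preds.append(p)
            golds.append(g)
        report = precision_recall(preds, golds)
        for cat in Category:
            tp = sum(
                1 for p, g in zip(preds, golds)
                if cat in p.categories and cat in g.categories
            )
            fp = sum(
                1 for p, g in zip(preds, golds)
                if cat in p.categories and cat not in g.categories
            )
            fn = sum(
                1 for p, g in zip(preds, golds)
                if cat not in p.categories and cat in g.categories
            )
            score = report.categories[cat]
            assert (score.tp, score.fp, score.fn) == (tp, fp, fn)
            gold_pos = sum(1 for g in golds if cat in g.categories)
            assert score.tp + score.fn == gold_pos


def test_permutation_invariance():
    rng = random.Random(99)
    pairs = [_pair(i, _random_cats(rng), _random_cats(rng)) for i in range(30)]
    preds = [p for p, _ in pairs]
    golds = [g for _, g in pairs]
    r1 = precision_recall(preds, golds)
    rng.shuffle(preds)
    rng.shuffle(golds)
    r2 = precision_recall(preds, golds)
    assert r1.as_dict() == r2.as_dict()


def test_zero_over_zero_reported_undefined():
    """A category with no predictions and no gold positives is flagged
    undefined, not silently scored."""
    pairs = [_pair(0, {Category.GENERAL_OTHER}, {Category.GENERAL_OTHER})]
    report = precision_recall([p for p, _ in pairs], [g for _, g in pairs])
    score = report.categories[Category.MYTHS_CONSPIRACY]
    assert not score.precision_defined
    assert not score.recall_defined
    assert math.isnan(score.precision) and math.isnan(score.recall)
    assert report.as_dict()["myths_conspiracy"]["precision"] is None


def test_mismatched_multisets_raise_join_error():
    p0, g0 = _pair(0, {Category.GENERAL_OTHER}, {Category.GENERAL_OTHER})
    _, g1 = _pair(1, {Category.GENERAL_OTHER}, {Category.GENERAL_OTHER})
    with pytest.raises(JoinError, match="unmatched"):
        precision_recall([p0], [g0, g1])


def test_duplicate_keys_raise_join_error():
    p0, g0 = _pair(0, {Category.GENERAL_OTHER}, {Category.GENERAL_OTHER})
    with pytest.raises(JoinError, match="duplicate"):
        precision_recall([p0, p0], [g0])


# ----------------------------------------------------------------- coverage


def _classified(text, cats, count=1):
    return ClassifiedQuery(
        record=QueryRecord(D0, text, count), categories=frozenset(cats)
    )


def test_coverage_all_specific_is_one():
    cqs = [_classified(f"cvs covid vaccine {i}", {Category.AVAILABILITY}) for i in range(5)]
    assert specific_coverage(cqs) == 1.0


def test_coverage_direct_fraction():
    cqs = [_classified(f"ny covid vaccine {i}", {Category.AVAILABILITY}) for i in range(90)]
    cqs += [_classified(f"unknown query {i}", {Category.GENERAL_OTHER}) for i in range(10)]
    assert specific_coverage(cqs) == pytest.approx(0.9)


def test_coverage_counts_explicit_general_patterns():
    cqs = [
        _classified("covid vaccine", {Category.GENERAL_OTHER}),
        _classified("mystery words", {Category.GENERAL_OTHER}),
    ]
    pats = [normalize_text("covid vaccine")]
    assert specific_coverage(cqs, general_patterns=pats) == pytest.approx(0.5)
    # exact-form matching: a longer query containing the pattern is residual
    cqs.append(_classified("covid vaccine mystery", {Category.GENERAL_OTHER}))
    assert specific_coverage(cqs, general_patterns=pats) == pytest.approx(1 / 3)


def test_coverage_volume_weighted_matches_weighted_oracle():
    rng = random.Random(31)
    cqs, covered_vol, total_vol = [], 0, 0
    for i in range(60):
        count = rng.randint(1, 40)
        if rng.random() < 0.7:
            cqs.append(_classified(f"texas covid vaccine {i}", {Category.AVAILABILITY}, count))
            covered_vol += count
        else:
            cqs.append(_classified(f"residual {i}", {Category.GENERAL_OTHER}, count))
        total_vol += count
    assert specific_coverage(cqs) == pytest.approx(covered_vol / total_vol)
    # unweighted variant counts queries, not volume
    unweighted = sum(
        1 for cq in cqs if cq.categories != frozenset({Category.GENERAL_OTHER})
    ) / len(cqs)
    assert specific_coverage(cqs, weighted=False) == pytest.approx(unweighted)


def test_coverage_monotone_in_patterns(small_classified, lexicon):
    base = specific_coverage(small_classified, lexicon=lexicon)
    fewer = specific_coverage(
        small_classified, general_patterns=lexicon.general_patterns[:2], lexicon=None
    )
    assert base >= fewer
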