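"""Rules-based multi-label classification of vaccine-related search queries.

A query is assigned every specific category (availability, manufacturer,
side effects/safety, myths/conspiracy) whose lexicon contains a matching
term; queries matching none fall back to the exclusive general/other
category.  Matching operates on normalized, variant-resolved token
sequences; multi-token patterns match as contiguous subsequences, which
keeps every assignment auditable via the matched-terms trace.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from collections.abc import Iterable, Sequence

from .lexicon import Lexicon, normalize_text, resolve_tokens
from .records import (
    Category,
    ClassifiedQuery,
    QueryRecord,
    SPECIFIC_CATEGORIES,
)

__all__ = [
    "DegenerateInputError",
    "is_study_query",
    "classify",
    "classify_log",
    "filter_study_log",
    "daily_topk",
]


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it cannot meaningfully process."""


def is_study_query(tokens: Sequence[str], lexicon: Lexicon) -> bool:
    """True iff the tokens contain both a covid-equivalent and a
    vaccine-equivalent term (after variant resolution).

    This implements the study inclusion filter: only queries mentioning
    both the disease and vaccination are in scope.
    """
    resolved = resolve_tokens(tuple(tokens), lexicon)
    has_covid = any(t in lexicon.filter_covid for t in resolved)
    has_vaccine = any(t in lexicon.filter_vaccine for t in resolved)
    return has_covid and has_vaccine


def _contains_subsequence(tokens: tuple[str, ...], pattern: tuple[str, ...]) -> bool:
    if len(pattern) == 1:
        return pattern[0] in tokens
    n, m = len(tokens), len(pattern)
    return any(tokens[i : i + m] == pattern for i in range(n - m + 1))


def _match_categories(
    tokens: tuple[str, ...], lexicon: Lexicon
) -> tuple[frozenset[Category], bool, tuple[tuple[str, Category], ...]]:
    token_set = set(tokens)
    fired: set[Category] = set()
    pharmacy = False
    matched: list[tuple[str, Category]] = []
    for cat in SPECIFIC_CATEGORIES:
        for pattern in lexicon.patterns.get(cat, ()):
            hit = (
                pattern[0] in token_set
                if len(pattern) == 1
                else _contains_subsequence(tokens, pattern)
            )
            if hit:
                fired.add(cat)
                matched.append((" ".join(pattern), cat))
                if cat is Category.AVAILABILITY and pattern in lexicon.pharmacy_names:
                    pharmacy = True
    if not fired:
        return frozenset({Category.GENERAL_OTHER}), False, ()
    return frozenset(fired), pharmacy, tuple(matched)


def classify(record: QueryRecord, lexicon: Lexicon) -> ClassifiedQuery:
    """Assign a query record to one or more categories.

    Every specific category whose lexicon matches is assigned; if none
    match, the exclusive fallback ``GENERAL_OTHER`` is assigned, so every
    query receives at least one category.  The pharmacy flag is set iff a
    pharmacy-name pattern fired (implying the availability category).

    Raises :class:`DegenerateInputError` if the query normalizes to an
    empty token sequence.
    """
    tokens = resolve_tokens(normalize_text(record.text), lexicon)
    if not tokens:
        raise DegenerateInputError(
            f"query {record.text!r} normalizes to an empty token sequence"
        )
    categories, pharmacy, matched = _match_categories(tokens, lexicon)
    return ClassifiedQuery(
        record=record, categories=categories, pharmacy=pharmacy, matched_terms=matched
    )


def classify_log(
    records: Iterable[QueryRecord], lexicon: Lexicon
) -> list[ClassifiedQuery]:
    """Classify a whole log, memoizing on query text.

    Classification is a pure function of the normalized text, so repeated
    query strings (the norm in daily top-k logs) are matched once.
    """
    cache: dict[str, tuple[frozenset[Category], bool, tuple[tuple[str, Category], ...]]] = {}
    out: list[ClassifiedQuery] = []
    for rec in records:
        hit = cache.get(rec.text)
        if hit is None:
            tokens = resolve_tokens(normalize_text(rec.text), lexicon)
            if not tokens:
                raise DegenerateInputError(
                    f"query {rec.text!r} normalizes to an empty token sequence"
                )
            hit = _match_categories(tokens, lexicon)
            cache[rec.text] = hit
        categories, pharmacy, matched = hit
        out.append(
            ClassifiedQuery(
                record=rec, categories=categories, pharmacy=pharmacy, matched_terms=matched
            )
        )
    return out


def filter_study_log(
    records: Iterable[QueryRecord], lexicon: Lexicon
) -> list[QueryRecord]:
    """Keep only records passing the covid+vaccine inclusion filter."""
    kept = []
    for rec in records:
        if is_study_query(normalize_text(rec.text), lexicon):
            kept.append(rec)
    return kept


def daily_topk(records: Iterable[QueryRecord], k: int) -> list[QueryRecord]:
    """Retain, per calendar date, the k records with the largest counts.

    Emulates daily top-k query-log sampling.  Ties in count are broken by
    ascending query text so the result is deterministic.  Output preserves
    date order, then descending count.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    by_day: dict[dt.date, list[QueryRecord]] = defaultdict(list)
    for rec in records:
        by_day[rec.date].append(rec)
    out: list[QueryRecord] = []
    for day in sorted(by_day):
        day_recs = sorted(by_day[day], key=lambda r: (-r.count, r.text))
        out.extend(day_recs[:k])
    return out
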