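"""Scoring classifier output against gold-standard labels.

Per-category precision and recall are computed one-vs-rest over the joined
(query, date) multiset: for category C a query is a true positive when C is
in both the predicted and gold sets, a false positive when predicted only,
a false negative when gold only.  The pharmacy flag is scored as its own
binary label.  A 0/0 precision or recall (no predictions, or no gold
positives) is reported as undefined with an explicit flag rather than
silently mapped to 0 or 1.

Coverage quantifies how much query volume the specific categories (plus an
explicit list of bare "general" query forms) account for — the complement
is the residual, truly unclassifiable "other" mass.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .lexicon import Lexicon, normalize_text, resolve_tokens
from .records import Category, ClassifiedQuery, GoldLabel

__all__ = ["CategoryScore", "EvalReport", "JoinError", "precision_recall", "specific_coverage"]


class JoinError(ValueError):
    """Predicted and gold label sets do not cover the same query multiset."""


@dataclass(frozen=True, slots=True)
class CategoryScore:
    """One-vs-rest confusion counts and derived scores for one label."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        """TP/(TP+FP); NaN when undefined (no predicted positives)."""
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        """TP/(TP+FN); NaN when undefined (no gold positives)."""
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def precision_defined(self) -> bool:
        return (self.tp + self.fp) > 0

    @property
    def recall_defined(self) -> bool:
        return (self.tp + self.fn) > 0


@dataclass(frozen=True)
class EvalReport:
    """Per-category scores plus the pharmacy-flag score."""

    categories: dict[Category, CategoryScore]
    pharmacy: CategoryScore
    n_queries: int

    def as_dict(self) -> dict:
        def entry(s: CategoryScore) -> dict:
            return {
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
                "precision": None if not s.precision_defined else s.precision,
                "recall": None if not s.recall_defined else s.recall,
            }

        out = {cat.value: entry(s) for cat, s in self.categories.items()}
        out["pharmacy"] = entry(self.pharmacy)
        out["n_queries"] = self.n_queries
        return out


def precision_recall(
    predicted: Iterable[ClassifiedQuery], gold: Iterable[GoldLabel]
) -> EvalReport:
    """Score predictions against gold labels joined on (date, query text).

    Raises :class:`JoinError`, listing orphans, if the two sides do not
    cover exactly the same query multiset.
    """
    pred_map: dict[tuple, ClassifiedQuery] = {}
    for cq in predicted:
        key = (cq.record.date, cq.record.text)
        if key in pred_map:
            raise JoinError(f"duplicate predicted entry for {key}")
        pred_map[key] = cq
    gold_map: dict[tuple, GoldLabel] = {}
    for gl in gold:
        key = (gl.date, gl.text)
        if key in gold_map:
            raise JoinError(f"duplicate gold entry for {key}")
        gold_map[key] = gl

    pred_only = sorted(set(pred_map) - set(gold_map))
    gold_only = sorted(set(gold_map) - set(pred_map))
    if pred_only or gold_only:
        raise JoinError(
            f"unmatched queries: {len(pred_only)} predicted-only "
            f"(e.g. {pred_only[:3]}), {len(gold_only)} gold-only "
            f"(e.g. {gold_only[:3]})"
        )

    counts = {cat: [0, 0, 0] for cat in Category}  # tp, fp, fn
    ph = [0, 0, 0]
    for key, cq in pred_map.items():
        gl = gold_map[key]
        for cat in Category:
            in_pred = cat in cq.categories
            in_gold = cat in gl.categories
            if in_pred and in_gold:
                counts[cat][0] += 1
            elif in_pred:
                counts[cat][1] += 1
            elif in_gold:
                counts[cat][2] += 1
        if cq.pharmacy and gl.pharmacy:
            ph[0] += 1
        elif cq.pharmacy:
            ph[1] += 1
        elif gl.pharmacy:
            ph[2] += 1

    return EvalReport(
        categories={cat: CategoryScore(*counts[cat]) for cat in Category},
        pharmacy=CategoryScore(*ph),
        n_queries=len(pred_map),
    )


def _matches_general(
    tokens: tuple[str, ...], general_patterns: Sequence[tuple[str, ...]]
) -> bool:
    # general patterns are exact whole-query forms, not substrings: a bare
    # "covid vaccine" query is general, "covid vaccine microchip" is not
    return tokens in general_patterns


def specific_coverage(
    predicted: Iterable[ClassifiedQuery],
    general_patterns: Sequence[tuple[str, ...]] | None = None,
    lexicon: Lexicon | None = None,
    weighted: bool = True,
) -> float:
    """Fraction of query volume classified beyond the pure fallback.

    A query counts as covered when its category set contains a specific
    category, or when its normalized (variant-resolved, if a lexicon is
    given) token sequence exactly equals one of the explicit bare general
    forms in ``general_patterns``.  The complement is the residual "other"
    mass.  Volume-weighted by default; ``weighted=False`` counts distinct
    query observations equally.
    """
    pats: tuple[tuple[str, ...], ...]
    if general_patterns is not None:
        pats = tuple(tuple(p) for p in general_patterns)
    elif lexicon is not None:
        pats = lexicon.general_patterns
    else:
        pats = ()

    covered = 0.0
    total = 0.0
    for cq in predicted:
        w = float(cq.record.count) if weighted else 1.0
        total += w
        if cq.categories != frozenset({Category.GENERAL_OTHER}):
            covered += w
        else:
            tokens = normalize_text(cq.record.text)
            if lexicon is not None:
                tokens = resolve_tokens(tokens, lexicon)
            if _matches_general(tokens, pats):
                covered += w
    if total == 0:
        raise ValueError("no queries to score")
    return covered / total
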