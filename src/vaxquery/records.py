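"""Core domain types for search-query-log analysis.

A query log is a collection of (date, query text, daily count) observations.
Each query is assigned to one or more of five content categories; queries
naming a specific pharmacy chain form a flagged subcategory of availability.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field


class Category(enum.Enum):
    """The five query-content categories.

    ``GENERAL_OTHER`` is the exclusive fallback: it is assigned exactly when
    none of the four specific categories match, and never co-occurs with
    them.  The four specific categories may co-occur freely (multi-label).
    """

    AVAILABILITY = "availability"
    MANUFACTURER = "manufacturer"
    SIDE_EFFECTS_SAFETY = "side_effects_safety"
    MYTHS_CONSPIRACY = "myths_conspiracy"
    GENERAL_OTHER = "general_other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed serialization order for category sets.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.AVAILABILITY,
    Category.MANUFACTURER,
    Category.SIDE_EFFECTS_SAFETY,
    Category.MYTHS_CONSPIRACY,
    Category.GENERAL_OTHER,
)

#: The four specific (non-fallback) categories, in serialization order.
SPECIFIC_CATEGORIES: tuple[Category, ...] = CATEGORY_ORDER[:-1]


def format_categories(categories: frozenset[Category] | set[Category]) -> str:
    """Serialize a category set as a semicolon-joined string in stable order."""
    return ";".join(c.value for c in CATEGORY_ORDER if c in categories)


def parse_categories(text: str) -> frozenset[Category]:
    """Parse a semicolon-joined category string back into a set."""
    parts = [p for p in text.strip().split(";") if p]
    return frozenset(Category(p) for p in parts)


@dataclass(frozen=True, slots=True)
class QueryRecord:
    """One (date, query, count) observation from a search log."""

    date: dt.date
    text: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")


def _validate_category_set(categories: frozenset[Category]) -> None:
    if not categories:
        raise ValueError("category set must be non-empty")
    if Category.GENERAL_OTHER in categories and len(categories) > 1:
        raise ValueError(
            "GENERAL_OTHER is an exclusive fallback and cannot co-occur "
            f"with other categories: {format_categories(categories)}"
        )


@dataclass(frozen=True, slots=True)
class ClassifiedQuery:
    """A query record together with its assigned categories.

    ``matched_terms`` records every (pattern, category) pair that fired,
    for auditability; it is empty exactly when the fallback applied.
    """

    record: QueryRecord
    categories: frozenset[Category]
    pharmacy: bool = False
    matched_terms: tuple[tuple[str, Category], ...] = field(default=())

    def __post_init__(self) -> None:
        _validate_category_set(self.categories)
        if self.pharmacy and Category.AVAILABILITY not in self.categories:
            raise ValueError("pharmacy flag requires the availability category")


@dataclass(frozen=True, slots=True)
class GoldLabel:
    """Reference (gold-standard) labels for one query observation."""

    date: dt.date
    text: str
    categories: frozenset[Category]
    pharmacy: bool = False

    def __post_init__(self) -> None:
        _validate_category_set(self.categories)
        if self.pharmacy and Category.AVAILABILITY not in self.categories:
            raise ValueError("pharmacy flag requires the availability category")
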