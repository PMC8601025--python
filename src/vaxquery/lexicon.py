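"""Lexicon loading, text normalization, and spelling-variant resolution.

The classifier is driven entirely by a lexicon: per-category term/phrase
lists, a pharmacy-name sublist of the availability terms, a curated
spelling-variant table, and the inclusion filter (covid-equivalent and
vaccine-equivalent terms).  A versioned default lexicon reconstructing the
published category vocabulary ships with the package; users supply their own
JSON file to extend or replace it.

Lexicon JSON schema (all strings lower-case)::

    {
      "version": "1.0",
      "filter_terms": {"covid": [...], "vaccine": [...]},
      "categories": {"availability": [...], "manufacturer": [...],
                     "side_effects_safety": [...], "myths_conspiracy": [...]},
      "pharmacy_names": [...],
      "variants": {"variant": "canonical", ...},
      "general_patterns": [...]
    }

``general_patterns`` is optional and lists exact normalized forms of
"bare" general queries, used by coverage accounting.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .records import Category, SPECIFIC_CATEGORIES

__all__ = [
    "Lexicon",
    "default_lexicon",
    "load_lexicon",
    "normalize_text",
    "resolve_variant",
    "resolve_tokens",
]

DEFAULT_LEXICON_RESOURCE = "lexicon_v1.json"

# Keep intra-token apostrophes ("sam's"); everything else non-alphanumeric
# becomes a token boundary, so hyphens and "&" split tokens.
_PUNCT_RE = re.compile(r"[^a-z0-9']+")
_COVID_DIGIT_RE = re.compile(r"\bcovid(\d)")


def normalize_text(raw: str) -> tuple[str, ...]:
    """Normalize a raw query string into a lower-case token sequence.

    Case is folded; punctuation other than intra-token apostrophes becomes
    whitespace (hyphens and ampersands therefore split tokens); digit-suffix
    spellings of covid ("covid19", "covid-19") normalize to the token pair
    ``("covid", "19")``.  Total: any string, including the empty string, is
    accepted.
    """
    text = raw.lower()
    text = _PUNCT_RE.sub(" ", text)
    text = _COVID_DIGIT_RE.sub(r"covid \1", text)
    tokens = (tok.strip("'") for tok in text.split())
    return tuple(tok for tok in tokens if tok)


@dataclass(frozen=True)
class Lexicon:
    """Category term lists plus filter terms and the variant table.

    Patterns are stored as token tuples; multi-token patterns match as
    contiguous token subsequences after variant resolution.
    """

    version: str
    filter_covid: frozenset[str]
    filter_vaccine: frozenset[str]
    patterns: dict[Category, tuple[tuple[str, ...], ...]]
    pharmacy_names: frozenset[tuple[str, ...]]
    variants: dict[str, str]
    general_patterns: tuple[tuple[str, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        for cat, pats in self.patterns.items():
            for pat in pats:
                if not pat or any(not tok for tok in pat):
                    raise ValueError(f"empty pattern in category {cat}")
                joined = " ".join(pat)
                if joined != joined.lower():
                    raise ValueError(f"pattern not lower-case: {joined!r}")
        avail = set(self.patterns.get(Category.AVAILABILITY, ()))
        missing = set(self.pharmacy_names) - avail
        if missing:
            raise ValueError(
                "pharmacy_names must be a subset of availability patterns; "
                f"missing: {sorted(' '.join(p) for p in missing)}"
            )

    @property
    def vocabulary(self) -> frozenset[str]:
        """All tokens appearing in any pattern or filter list."""
        toks: set[str] = set(self.filter_covid) | set(self.filter_vaccine)
        for pats in self.patterns.values():
            for pat in pats:
                toks.update(pat)
        return frozenset(toks)

    def with_pattern(self, category: Category, pattern: str) -> "Lexicon":
        """Return a copy with one extra pattern added to ``category``."""
        pats = dict(self.patterns)
        pats[category] = pats.get(category, ()) + (normalize_text(pattern),)
        return Lexicon(
            version=self.version,
            filter_covid=self.filter_covid,
            filter_vaccine=self.filter_vaccine,
            patterns=pats,
            pharmacy_names=self.pharmacy_names,
            variants=self.variants,
            general_patterns=self.general_patterns,
        )


def resolve_variant(token: str, lexicon: Lexicon) -> str:
    """Map a token to its canonical spelling, or return it unchanged."""
    return lexicon.variants.get(token, token)


def resolve_tokens(tokens: tuple[str, ...], lexicon: Lexicon) -> tuple[str, ...]:
    """Apply variant resolution to every token of a normalized sequence."""
    return tuple(lexicon.variants.get(t, t) for t in tokens)


def _parse_patterns(items: list[str]) -> tuple[tuple[str, ...], ...]:
    out = []
    for item in items:
        if not item:
            raise ValueError("empty pattern string in lexicon")
        out.append(tuple(item.split()))
    return tuple(out)


def _from_dict(data: dict) -> Lexicon:
    cat_key = {
        Category.AVAILABILITY: "availability",
        Category.MANUFACTURER: "manufacturer",
        Category.SIDE_EFFECTS_SAFETY: "side_effects_safety",
        Category.MYTHS_CONSPIRACY: "myths_conspiracy",
    }
    patterns = {
        cat: _parse_patterns(data["categories"][key])
        for cat, key in cat_key.items()
    }
    variants = dict(data.get("variants", {}))
    for variant, canonical in variants.items():
        if not variant or not canonical:
            raise ValueError("empty entry in variant table")
    return Lexicon(
        version=str(data.get("version", "unversioned")),
        filter_covid=frozenset(data["filter_terms"]["covid"]),
        filter_vaccine=frozenset(data["filter_terms"]["vaccine"]),
        patterns=patterns,
        pharmacy_names=frozenset(_parse_patterns(data.get("pharmacy_names", []))),
        variants=variants,
        general_patterns=_parse_patterns(data.get("general_patterns", [])),
    )


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from a JSON file."""
    with open(path, encoding="utf-8") as fh:
        return _from_dict(json.load(fh))


def default_lexicon() -> Lexicon:
    """Load the versioned lexicon bundled with the package."""
    ref = resources.files("vaxquery.data").joinpath(DEFAULT_LEXICON_RESOURCE)
    return _from_dict(json.loads(ref.read_text(encoding="utf-8")))


# sanity check used by tests and the loader: every specific category must
# have at least one pattern, otherwise classification is vacuous
def category_pattern_counts(lexicon: Lexicon) -> dict[Category, int]:
    return {cat: len(lexicon.patterns.get(cat, ())) for cat in SPECIFIC_CATEGORIES}
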