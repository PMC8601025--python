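"""Seeded synthetic query-log generator with known gold labels.

Real vaccine-related search logs are proprietary, so every pipeline stage
is exercised on generated logs that reproduce the statistical structure the
analysis assumes:

* a heavy-tailed (Zipfian, weight_i proportional to i^-s) popularity
  distribution over a fixed universe of distinct query strings per
  category;
* per-category volume shares that follow configurable linear weekly
  trajectories (category shares partition expected volume; multi-label
  mass enters only through an explicit composite stratum of
  pharmacy-plus-manufacturer queries at a configurable rate);
* optional per-day top-k truncation, emulating top-k log sampling;
* optional label-transfer noise on the gold labels, for testing the
  evaluation harness.

Query strings are built from category template grammars over the shipped
lexicon vocabulary, so the gold category of every string is its grammar's
category by construction.  Generation is fully reproducible from the seed;
random streams are split per day and per purpose, so changing one
configuration field does not perturb unrelated draws.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .classifier import daily_topk
from .records import Category, GoldLabel, QueryRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticLog",
    "zipf_weights",
    "generate_log",
    "study_scenario",
    "inject_label_noise",
    "GENERATOR_VERSION",
]

GENERATOR_VERSION = "1.0"

# ---------------------------------------------------------------------------
# Template grammars.  Each stratum enumerates distinct query strings in a
# fixed deterministic order; Zipf popularity rank follows that order.

_STATES = [
    "california", "texas", "florida", "new york", "pennsylvania", "illinois",
    "ohio", "georgia", "north carolina", "michigan", "new jersey", "virginia",
    "washington", "arizona", "massachusetts", "tennessee", "indiana",
    "missouri", "maryland", "wisconsin", "colorado", "minnesota",
    "south carolina", "alabama", "louisiana", "kentucky", "oregon",
    "oklahoma", "connecticut", "utah", "iowa", "nevada", "arkansas",
    "mississippi", "kansas", "new mexico", "nebraska", "idaho",
    "west virginia", "hawaii", "new hampshire", "maine", "montana",
    "rhode island", "delaware", "south dakota", "north dakota", "alaska",
    "vermont", "wyoming",
]
_CITIES = [
    "nyc", "los angeles", "chicago", "houston", "phoenix", "philadelphia",
    "san antonio", "san diego", "dallas", "austin", "seattle", "denver",
    "boston", "atlanta", "miami", "detroit", "minneapolis", "las vegas",
    "portland", "san francisco",
]
_PHARMACIES = [
    "cvs", "walgreens", "rite aid", "walmart", "kroger", "costco", "publix",
    "safeway", "meijer", "heb", "wegmans", "albertsons",
]
_MANUFACTURERS = [
    "pfizer", "moderna", "johnson", "j&j", "janssen", "astrazeneca",
    "novavax", "biontech",
]
_SIDE_TERMS = [
    "side effects", "safety", "reaction", "blood clot", "fever", "allergy",
    "headache", "fatigue", "chills", "nausea", "rash", "sore arm",
    "myocarditis", "risks", "problems", "pregnancy",
]
_MYTH_QUERIES = [
    "covid vaccine infertility",
    "does covid vaccine change dna",
    "covid vaccine microchip",
    "can i get covid from vaccine",
    "covid vaccine 5g",
    "covid vaccine dna",
    "covid vaccine magnet",
    "covid vaccine sterility",
    "covid vaccine infertile",
]
# General stratum interleaves explicit bare forms (odd ranks, covered by
# the lexicon's general-pattern list) with residual informational queries
# (even ranks) that no pattern covers, so coverage accounting sees a
# realistic unclassifiable remainder.
_GENERAL_QUERIES = [
    "covid vaccine",
    "how long does the covid vaccine last",
    "covid 19 vaccine",
    "covid vaccine second dose",
    "coronavirus vaccine",
    "covid vaccination rates",
    "covid vaccine update",
    "covid vaccine questions",
    "covid vaccine news",
    "does the covid vaccine work",
    "the covid vaccine",
    "covid vaccine after effects",
    "new covid vaccine",
    "covid vaccine development",
]


def _availability_universe(n: int) -> list[str]:
    fixed = [
        "covid vaccine near me",
        "where to get covid vaccine",
        "when can i get covid vaccine",
        "covid vaccine appointment",
        "how to get covid vaccine",
        "covid vaccine sign up",
        "covid vaccine locations",
        "covid vaccine eligibility",
        "covid vaccine finder",
        "covid vaccine registration",
    ]
    locs = _STATES + _CITIES
    templated = []
    for loc in locs:
        templated.append(f"{loc} covid vaccine")
        templated.append(f"covid vaccine {loc}")
        templated.append(f"covid vaccine appointment {loc}")
        templated.append(f"covid vaccine eligibility {loc}")
    return _take("availability", fixed + templated, n)


def _pharmacy_universe(n: int) -> list[str]:
    out = []
    for ph in _PHARMACIES:
        out.append(f"{ph} covid vaccine")
        out.append(f"covid vaccine {ph}")
        out.append(f"{ph} covid vaccine appointment")
        out.append(f"covid vaccine appointment {ph}")
    return _take("pharmacy", out, n)


def _composite_universe(n: int) -> list[str]:
    out = []
    for manu in _MANUFACTURERS:
        for ph in _PHARMACIES:
            out.append(f"{manu} covid vaccine {ph}")
    return _take("composite", out, n)


def _manufacturer_universe(n: int) -> list[str]:
    out = []
    for manu in _MANUFACTURERS:
        out.append(f"{manu} covid vaccine")
        out.append(f"covid vaccine {manu}")
        out.append(f"{manu} covid 19 vaccine")
    return _take("manufacturer", out, n)


def _side_effects_universe(n: int) -> list[str]:
    out = []
    for term in _SIDE_TERMS:
        out.append(f"covid vaccine {term}")
        out.append(f"covid 19 vaccine {term}")
    return _take("side_effects_safety", out, n)


def _take(name: str, pool: list[str], n: int) -> list[str]:
    if n > len(pool):
        raise ValueError(
            f"universe_size[{name!r}]={n} exceeds the {len(pool)} distinct "
            "strings the template grammar can produce"
        )
    return pool[:n]


#: Gold label sets by stratum.
_STRATA = (
    "availability",
    "pharmacy",
    "composite",
    "manufacturer",
    "side_effects_safety",
    "myths_conspiracy",
    "general_other",
)
_STRATUM_GOLD: dict[str, tuple[frozenset[Category], bool]] = {
    "availability": (frozenset({Category.AVAILABILITY}), False),
    "pharmacy": (frozenset({Category.AVAILABILITY}), True),
    "composite": (
        frozenset({Category.AVAILABILITY, Category.MANUFACTURER}),
        True,
    ),
    "manufacturer": (frozenset({Category.MANUFACTURER}), False),
    "side_effects_safety": (frozenset({Category.SIDE_EFFECTS_SAFETY}), False),
    "myths_conspiracy": (frozenset({Category.MYTHS_CONSPIRACY}), False),
    "general_other": (frozenset({Category.GENERAL_OTHER}), False),
}

_DEFAULT_UNIVERSE = {
    "availability": 240,
    "pharmacy": 40,
    "composite": 32,
    "manufacturer": 24,
    "side_effects_safety": 32,
    "myths_conspiracy": 9,
    "general_other": 14,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    ``shares`` gives (start, end) weekly volume shares for the four
    specific categories; the availability share includes the pharmacy
    subcategory, whose own (start, end) trajectory of *total* volume is
    ``pharmacy_share``.  General/other receives the remainder, so the
    category shares partition expected volume at every week.  A fraction
    ``composite_rate`` of pharmacy volume is drawn from composite
    (pharmacy + manufacturer name) query strings, the only multi-label
    stratum.
    """

    n_weeks: int = 10
    start_date: dt.date = dt.date(2021, 1, 1)
    queries_per_day: int = 600_000
    universe_size: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_UNIVERSE)
    )
    zipf_exponent: float = 1.0
    shares: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "availability": (0.62, 0.62),
            "manufacturer": (0.104, 0.104),
            "side_effects_safety": (0.057, 0.042),
            "myths_conspiracy": (0.004, 0.001),
        }
    )
    pharmacy_share: tuple[float, float] = (0.059, 0.272)
    composite_rate: float = 0.05
    label_noise: float = 0.0
    topk: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError(f"n_weeks must be >= 1, got {self.n_weeks}")
        if self.queries_per_day < 0:
            raise ValueError("queries_per_day must be non-negative")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if not (0 <= self.label_noise < 1):
            raise ValueError("label_noise must lie in [0, 1)")
        if not (0 <= self.composite_rate <= 1):
            raise ValueError("composite_rate must lie in [0, 1]")
        for name in ("availability", "manufacturer", "side_effects_safety",
                     "myths_conspiracy"):
            if name not in self.shares:
                raise ValueError(f"missing share trajectory for {name!r}")
        # shares are linear in week index, so validating both endpoints
        # validates every week
        for w in (0, self.n_weeks - 1):
            p = self.stratum_shares(w)
            for name, v in p.items():
                if not (0 <= v <= 1):
                    raise ValueError(
                        f"stratum share {name!r}={v:.4f} outside [0,1] at week {w}"
                    )
        for name in _STRATA:
            if self.universe_size.get(name, 0) < 1:
                raise ValueError(f"empty query universe for stratum {name!r}")

    def share_at(self, name: str, week: int) -> float:
        """Linear interpolation of a category share at a week index."""
        start, end = (
            self.pharmacy_share if name == "pharmacy" else self.shares[name]
        )
        if self.n_weeks == 1:
            return start
        frac = week / (self.n_weeks - 1)
        return start + (end - start) * frac

    def stratum_shares(self, week: int) -> dict[str, float]:
        """Expected volume share of each sampling stratum at a week."""
        avail = self.share_at("availability", week)
        pharm = self.share_at("pharmacy", week)
        if pharm > avail:
            raise ValueError(
                f"pharmacy share {pharm:.4f} exceeds availability share "
                f"{avail:.4f} at week {week}"
            )
        manuf = self.share_at("manufacturer", week)
        side = self.share_at("side_effects_safety", week)
        myths = self.share_at("myths_conspiracy", week)
        general = 1.0 - (avail + manuf + side + myths)
        if general < -1e-12:
            raise ValueError(f"category shares exceed 1 at week {week}")
        return {
            "availability": avail - pharm,
            "pharmacy": pharm * (1.0 - self.composite_rate),
            "composite": pharm * self.composite_rate,
            "manufacturer": manuf,
            "side_effects_safety": side,
            "myths_conspiracy": myths,
            "general_other": max(general, 0.0),
        }

    @property
    def n_days(self) -> int:
        return 7 * self.n_weeks

    @property
    def window(self) -> tuple[dt.date, dt.date]:
        return (
            self.start_date,
            self.start_date + dt.timedelta(days=self.n_days - 1),
        )


@dataclass(frozen=True)
class SyntheticLog:
    """A generated log with its gold labels and configuration echo."""

    records: tuple[QueryRecord, ...]
    gold: tuple[GoldLabel, ...]
    config: SyntheticConfig
    generator_version: str = GENERATOR_VERSION


def zipf_weights(n: int, s: float) -> np.ndarray:
    """Normalized Zipf weights: weight_i proportional to i^-s, i = 1..n.

    The returned vector sums to 1 and is strictly decreasing for s > 0.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if s <= 0:
        raise ValueError(f"s must be > 0, got {s}")
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-s)
    return w / w.sum()


_UNIVERSE_BUILDERS = {
    "availability": _availability_universe,
    "pharmacy": _pharmacy_universe,
    "composite": _composite_universe,
    "manufacturer": _manufacturer_universe,
    "side_effects_safety": _side_effects_universe,
    "myths_conspiracy": lambda n: _take("myths_conspiracy", _MYTH_QUERIES, n),
    "general_other": lambda n: _take("general_other", _GENERAL_QUERIES, n),
}


def build_universes(config: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic per-stratum query-string universes (rank order fixed)."""
    return {
        name: _UNIVERSE_BUILDERS[name](config.universe_size[name])
        for name in _STRATA
    }


def _day_rng(seed: int, day: int, purpose: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(purpose, day))
    )


def generate_log(config: SyntheticConfig) -> SyntheticLog:
    """Generate a gold-labeled synthetic query log.

    For each day, the day's expected category shares are the linear
    interpolation of the configured trajectories at the day's week index
    (shares are constant within a week).  The day's total volume is split
    multinomially across strata, then across each stratum's Zipfian query
    universe; one record is emitted per (day, distinct query) with a
    positive draw.  Optional label-transfer noise and per-day top-k
    truncation are applied last.
    """
    universes = build_universes(config)
    weights = {
        name: zipf_weights(len(universes[name]), config.zipf_exponent)
        for name in _STRATA
    }

    records: list[QueryRecord] = []
    gold: list[GoldLabel] = []
    for day in range(config.n_days):
        if config.queries_per_day == 0:
            continue
        date = config.start_date + dt.timedelta(days=day)
        week = day // 7
        shares = config.stratum_shares(week)
        p = np.array([shares[name] for name in _STRATA])
        p = p / p.sum()
        rng = _day_rng(config.seed, day, purpose=0)
        stratum_counts = rng.multinomial(config.queries_per_day, p)
        for name, n_strat in zip(_STRATA, stratum_counts):
            if n_strat == 0:
                continue
            counts = rng.multinomial(n_strat, weights[name])
            cats, pharm = _STRATUM_GOLD[name]
            for qi in np.nonzero(counts)[0]:
                text = universes[name][qi]
                rec = QueryRecord(date=date, text=text, count=int(counts[qi]))
                records.append(rec)
                gold.append(
                    GoldLabel(
                        date=date, text=text, categories=cats, pharmacy=pharm
                    )
                )

    if config.label_noise > 0:
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
        )
        gold = inject_label_noise(gold, config.label_noise, noise_rng)

    if config.topk is not None:
        kept = daily_topk(records, config.topk)
        gold_map = {(g.date, g.text): g for g in gold}
        gold = [gold_map[(r.date, r.text)] for r in kept]
        records = kept

    return SyntheticLog(
        records=tuple(records), gold=tuple(gold), config=config
    )


def inject_label_noise(
    gold: list[GoldLabel] | tuple[GoldLabel, ...],
    rate: float,
    rng: np.random.Generator,
) -> list[GoldLabel]:
    """Perturb gold labels by per-category label transfer at the given rate.

    For each category independently, every gold-positive record donates its
    label with probability ``rate`` to a uniformly chosen record that lacks
    the category.  The per-category count of gold positives is preserved,
    and against a classifier that reproduces the clean labels, both the
    false negatives and false positives of category C are Binomial(N_C,
    rate), so measured recall and precision are each centred on 1 - rate
    with binomial sampling error.  (Fallback adjustments keep the
    general/other exclusivity invariant, so the general category's own
    scores are approximate, not exact.)

    The pharmacy flag follows the availability label: a record donating
    availability loses the flag; recipients do not gain it.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    sets = [set(g.categories) for g in gold]
    pharm = [g.pharmacy for g in gold]
    n = len(gold)
    for cat in Category:
        if cat is Category.GENERAL_OTHER:
            continue
        positives = [i for i, s in enumerate(sets) if cat in s]
        if not positives:
            continue
        flips = np.nonzero(rng.random(len(positives)) < rate)[0]
        negatives = [i for i, s in enumerate(sets) if cat not in s]
        if len(flips) == 0:
            continue
        if len(flips) > len(negatives):
            raise ValueError(
                f"cannot transfer {len(flips)} {cat.value} labels onto only "
                f"{len(negatives)} negative records; lower the noise rate"
            )
        # distinct recipients keep the per-category false-negative count
        # exactly Binomial(N_C, rate)
        recipients = rng.choice(len(negatives), size=len(flips), replace=False)
        for f, r in zip(flips, recipients):
            donor = positives[f]
            recipient = negatives[r]
            sets[donor].discard(cat)
            if cat is Category.AVAILABILITY:
                pharm[donor] = False
            if not sets[donor]:
                sets[donor] = {Category.GENERAL_OTHER}
            sets[recipient].discard(Category.GENERAL_OTHER)
            sets[recipient].add(cat)
    return [
        GoldLabel(
            date=g.date,
            text=g.text,
            categories=frozenset(s),
            pharmacy=ph and Category.AVAILABILITY in s,
        )
        for g, s, ph in zip(gold, sets, pharm)
    ]


def study_scenario(**overrides) -> SyntheticConfig:
    """Preset 10-week scenario mirroring the reported study magnitudes.

    Weekly volume shares: availability flat at 62% (the middle of the
    reported 55-69% weekly range), with its pharmacy subcategory rising
    linearly from 5.9% to 27.2% of total volume; manufacturer flat at
    10.4%; side effects/safety falling from 5.7% to 4.2%; myths falling
    from 0.4% to 0.1%; general/other takes the remainder.  Ten 7-day weeks
    from 2021-01-01, daily top-5000 truncation, Zipf exponent 1.
    """
    base = dict(
        n_weeks=10,
        start_date=dt.date(2021, 1, 1),
        queries_per_day=600_000,
        topk=5000,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def expected_weekly_shares(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Analytic expected weekly shares per category (classifier view).

    The composite stratum is multi-label, so the expected *measured*
    manufacturer share is the configured share plus composite_rate times
    the pharmacy share; all other categories equal their configured
    trajectories.
    """
    weeks = np.arange(config.n_weeks)
    out: dict[str, np.ndarray] = {}
    for name in ("availability", "manufacturer", "side_effects_safety",
                 "myths_conspiracy"):
        out[name] = np.array([config.share_at(name, int(w)) for w in weeks])
    out["pharmacy"] = np.array(
        [config.share_at("pharmacy", int(w)) for w in weeks]
    )
    out["manufacturer"] = (
        out["manufacturer"] + config.composite_rate * out["pharmacy"]
    )
    out["general_other"] = 1.0 - (
        out["availability"]
        + np.array([config.share_at("manufacturer", int(w)) for w in weeks])
        + out["side_effects_safety"]
        + out["myths_conspiracy"]
    )
    return out


def config_to_dict(config: SyntheticConfig) -> dict:
    """JSON-serializable echo of a configuration."""
    d = dataclasses.asdict(config)
    d["start_date"] = config.start_date.isoformat()
    d["universe_size"] = dict(config.universe_size)
    d["shares"] = {k: list(v) for k, v in config.shares.items()}
    d["pharmacy_share"] = list(config.pharmacy_share)
    d["generator_version"] = GENERATOR_VERSION
    return d
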