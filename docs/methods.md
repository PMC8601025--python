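# Methods

## Problem and model

`vaxquery` analyses search-query logs about COVID-19 vaccination. A log is
a set of (date, query text, daily count) observations. The analysis has
four stages:

1. **Inclusion filter.** A query is in scope when it contains both a
   covid-equivalent term (covid, coronavirus, corona) and a
   vaccine-equivalent term (vaccine, vax — with vaccines / vaccination(s) /
   vaccinated folded in by the variant table). This is deliberately a
   token-level, not substring, test.
2. **Rules-based multi-label classification.** Each query is normalized
   (case folding; punctuation other than intra-token apostrophes becomes a
   token boundary; `covid19`/`covid-19` → `covid 19`), variant-resolved
   against a curated misspelling table, and matched against per-category
   term lists: *availability* (place names, scheduling/eligibility
   phrases, pharmacy chains), *manufacturer*, *side effects / safety*,
   *myths / conspiracy*. Multi-token patterns match as contiguous token
   subsequences. A query receives every category that matches; a query
   matching none falls back to the exclusive *general/other* category, so
   assignment is total. Queries matching a pharmacy-chain name form a
   flagged subcategory of availability, a marker of active intent to
   obtain vaccination.
3. **Weekly proportions and trends.** Volume is aggregated into
   consecutive 7-day blocks anchored at the study start (a trailing
   partial block is dropped; an anchored 75-day window therefore yields 10
   weekly points and df = 8 trend fits). The share of a category in a week
   is the volume of queries carrying the category divided by total week
   volume; multi-label queries count fully in each of their categories, so
   specific shares may overlap while `general_other` + (share with ≥ 1
   specific category) = 1. Each share series, in percent, is regressed on
   week index by ordinary least squares; we report slope β (percentage
   points per week), intercept, R², df = n − 2, and the two-sided slope
   t-test p-value. A constant response returns β = 0, R² = 0 with a
   degenerate flag rather than an error; a constant predictor is an error.
   No autocorrelation correction or multiple-testing adjustment is
   applied: each category is a separate descriptive fit.
4. **Relative search volume (RSV).** One or more count series are scaled
   by 100 / (global maximum over all provided series), so the joint peak
   is exactly 100 and series become comparable on the 0–100 scale.
   Values keep full float precision; an integer-rounding mode mimics
   public trend tools. Scale invariance (rescaling all counts by c > 0
   changes nothing) holds by construction.

## The shipped lexicon

The published vocabulary gives term *families* with examples, not
exhaustive lists, so the bundled `lexicon_v1.json` is a reconstruction:
all 50 US state names plus an unambiguous subset of postal abbreviations
(two-letter codes such as "in", "or", "me", "la" collide with ordinary
query words and are excluded), 20 large cities, a pharmacy-chain list,
manufacturer names, side-effect and safety terms, and the five myth themes
(infertility, DNA alteration, 5G, microchips, contracting the disease from
the vaccine). The variant table is an explicit curated map (no fuzzy
matching): reported classifier precision of ~100% implies conservative
matching, and edit-distance rules would silently over-match. Users pass
their own JSON to extend any list; the loader enforces lower-case
patterns, non-empty entries, and pharmacy ⊆ availability.

## Evaluation conventions

Precision and recall are per-category one-vs-rest over the (date, query)
join of predictions and gold labels; the pharmacy flag is scored as its
own binary label. 0/0 ratios are reported as undefined with a flag, never
silently 0 or 1. *Specific coverage* is the volume-weighted fraction of
queries that either carry a specific category or exactly equal one of the
explicit bare general forms ("covid vaccine", "coronavirus vaccine", …);
the complement is the residual, truly unclassifiable mass. Exact-form
matching is essential: every in-scope query contains "covid vaccine" as a
subsequence, so substring matching would make coverage vacuously 1.

## Synthetic data generator

Real query logs are proprietary, so the generator produces gold-labeled
logs with the structure the analysis assumes:

* **Popularity.** Each category has a fixed universe of distinct query
  strings built from template grammars over the lexicon (e.g.
  "{pharmacy} covid vaccine appointment"), guaranteeing that the gold
  label of a string is its grammar's category. Within a universe, query
  popularity is Zipfian: weight_i ∝ i^(−s), default s = 1.
* **Trends.** Weekly category shares interpolate linearly between
  configured start and end values, constant within a week; daily volume is
  split multinomially across strata, then across each stratum's universe.
  Expected weekly shares are therefore exactly the configured trajectories
  and the weekly-share estimator is unbiased (week volume is fixed at
  7 × queries_per_day).
* **Multi-label mass.** Category shares partition expected volume; overlap
  enters only through an explicit composite stratum — pharmacy queries
  that also name a manufacturer — carrying a configurable fraction
  (default 5%) of pharmacy volume. Anchoring the composite inside the
  pharmacy stratum keeps the availability and pharmacy trajectories
  exactly as configured; the measured manufacturer share is analytically
  configured + 0.05 × pharmacy share.
* **General stratum.** Bare general forms (odd Zipf ranks) interleave with
  residual informational queries no pattern covers (even ranks, e.g. "how
  long does the covid vaccine last"), so coverage accounting sees a
  realistic unclassifiable remainder (~9% of total volume under the
  default scenario).
* **Label noise.** For evaluation tests, gold labels can be perturbed by
  *label transfer*: per category independently, each gold-positive record
  donates its label with probability ε to a distinct, uniformly chosen
  record lacking the category. This preserves each category's
  gold-positive count and makes the per-category false-negative count
  exactly Binomial(N_C, ε), so measured recall and precision are both
  centred on 1 − ε with binomial sampling error — generic "resample the
  label" noise models instead converge to 1 − ε(1 − p_C), which is
  distorted for high-share categories. Fallback bookkeeping (a record
  losing its last label becomes general) makes the general category's own
  noisy scores approximate; tests therefore check the specific categories.
* **Determinism.** Random streams are split per day and per purpose from
  the master seed (`SeedSequence(seed, spawn_key=(purpose, day))`);
  identical config + seed gives byte-identical output files.

The preset `study_scenario()` encodes the study conditions: ten 7-day
weeks from 2021-01-01; 600,000 queries/day (≈ 45.4M over the window at the
published scale); daily top-5000 truncation; availability flat at 62% (the
middle of the reported 55–69% weekly range) with its pharmacy subcategory
rising 5.9% → 27.2% of total volume; manufacturer flat at 10.4%; side
effects 5.7% → 4.2%; myths 0.4% → 0.1%; general takes the remainder.
Intermediate weekly values are linear between those endpoints by
construction — the preset reproduces published endpoint magnitudes, not
the unpublished weekly curves.

## Problem sizes used in tests and the acceptance run

Slope-recovery and noise tests run the scenario at 50,000 queries/day over
20 seeds (multinomial sampling cost is independent of volume, and
classification is memoized per distinct string, so a full pipeline pass
takes well under a second); the acceptance script runs the full 600,000
queries/day preset. These sizes were chosen so sampling error is far below
the effect sizes being recovered.

## What passing tests do and do not show

The generator emits exactly lexicon-covered strings, so perfect
precision/recall on clean synthetic logs validates the *mechanics* of
matching and scoring, not the real-world completeness of the reconstructed
vocabulary. Likewise the generator has no query reformulation, geography,
seasonality, or autocorrelated noise; recovering configured slopes shows
the estimator chain is unbiased under the stated sampling model, not that
real search trends are linear. Concentration statistics (top-150 volume
share) are computed over a few hundred distinct synthetic strings versus
millions of real queries, so they are structurally higher than the
published figure.

## Numerical and design choices

* Week bucketing is anchored 7-day blocks, not ISO weeks: the published
  df = 8 implies 10 weekly points over a 75-day window, which only anchored
  blocks reproduce.
* Proportions are volume-weighted (by daily counts), not query-distinct:
  the analysed object is query volume sampled as daily top-k lists.
* `daily_topk` breaks count ties by ascending query text for determinism.
* OLS is delegated to `scipy.stats.linregress`; tests verify equivalence
  with the closed-form Σxy/Σxx solution (including the slope-t p-value) to
  1e-10.
* All dates are ISO-8601, all files UTF-8; category sets serialize in the
  fixed order availability, manufacturer, side_effects_safety,
  myths_conspiracy, general_other. Floats in CSV artifacts are written via
  `repr` and parsed with round-trip precision, so file round-trips are
  bit-exact.

## Known limitations

* The lexicon is a reconstruction; on real logs its coverage would need
  re-auditing against a manual sample.
* The classifier is purely lexical: negations ("is the covid vaccine not
  safe") and questions land in the same category as their keywords.
* The trend model is descriptive OLS on ≤ 10 points; it is not a
  forecasting or changepoint model, and weekly shares are compositional
  (categories compete), which the independent per-category fits ignore —
  as the original analysis does.
* RSV emulation covers only peak normalization, not the sampling and
  integer bucketing of public trend tools (an optional rounding mode
  approximates the latter).
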