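#!/usr/bin/env python
"""Filter and classify the scenario log with the shipped lexicon.

Applies the covid+vaccine inclusion filter, then the rules-based
multi-label classifier, and reports per-category volume totals.  Writes
the classified TSV under results/data/.
"""

import argparse
from collections import Counter
from pathlib import Path

from vaxquery import (
    Category,
    classify_log,
    default_lexicon,
    filter_study_log,
)
from vaxquery.io import read_query_log, write_classified

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
args = parser.parse_args()

lexicon = default_lexicon()
records = read_query_log(args.data_dir / "scenario.log.tsv")
kept = filter_study_log(records, lexicon)
print(f"inclusion filter: {len(kept)}/{len(records)} records retained")

classified = classify_log(kept, lexicon)
write_classified(classified, args.data_dir / "scenario.classified.tsv")

volume = Counter()
for cq in classified:
    for cat in cq.categories:
        volume[cat] += cq.record.count
    if cq.pharmacy:
        volume["pharmacy"] += cq.record.count
total = sum(cq.record.count for cq in classified)
print(f"classified {len(classified)} records ({total:,} volume); "
      "category volume shares:")
for cat in Category:
    print(f"  {cat.value:<20s} {100 * volume[cat] / total:6.2f}%")
print(f"  {'pharmacy (subcat.)':<20s} {100 * volume['pharmacy'] / total:6.2f}%")
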