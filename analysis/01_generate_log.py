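#!/usr/bin/env python
"""Generate the study-scenario synthetic query log.

Ten 7-day weeks from 2021-01-01 at 600k queries/day with daily top-5000
sampling: availability flat at 62% with the pharmacy subcategory rising
5.9% -> 27.2%, manufacturer flat at 10.4%, side effects falling 5.7% ->
4.2%, myths falling 0.4% -> 0.1%, remainder general.  Writes the log, its
gold labels, and a config echo under results/data/.
"""

import argparse
import json
from pathlib import Path

from vaxquery import generate_log, study_scenario
from vaxquery.io import write_gold, write_query_log
from vaxquery.synthetic import config_to_dict

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("scratch/data"))
args = parser.parse_args()

cfg = study_scenario(seed=args.seed)
log = generate_log(cfg)

args.out_dir.mkdir(parents=True, exist_ok=True)
write_query_log(log.records, args.out_dir / "scenario.log.tsv")
write_gold(log.gold, args.out_dir / "scenario.gold.tsv")
(args.out_dir / "scenario.config.json").write_text(
    json.dumps(config_to_dict(cfg), indent=2, sort_keys=True) + "\n"
)

volume = sum(r.count for r in log.records)
print(f"generated {len(log.records)} records over {cfg.n_days} days "
      f"({volume:,} total query volume, seed={args.seed})")
print(f"wrote scenario.log.tsv / scenario.gold.tsv to {args.out_dir}")
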