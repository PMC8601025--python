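#!/usr/bin/env python
"""Weekly category proportions and per-category linear time trends.

Aggregates the classified scenario log into 10 weekly volume-weighted
share vectors and fits each category's share-vs-week OLS trend, reported
as (df, R^2, beta, p) with shares in percent.  Writes the weekly table
and trend JSON under results/.
"""

import argparse
import datetime as dt
import json
from pathlib import Path

from vaxquery import fit_all_trends, weekly_shares
from vaxquery.io import read_classified, write_trend_results, write_weekly_shares

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
parser.add_argument("--start", type=dt.date.fromisoformat,
                    default=dt.date(2021, 1, 1))
parser.add_argument("--end", type=dt.date.fromisoformat,
                    default=dt.date(2021, 3, 11))
args = parser.parse_args()

classified = read_classified(args.data_dir / "scenario.classified.tsv")
weeks = weekly_shares(classified, (args.start, args.end))
trends = fit_all_trends(weeks)

args.out_dir.mkdir(parents=True, exist_ok=True)
write_weekly_shares(weeks, args.out_dir / "weekly_shares.csv")
write_trend_results(trends, args.out_dir / "trend_results.json")

print(f"{len(weeks)} weekly points from {args.start} "
      f"(trailing partial week dropped)")
print(f"{'series':<22s}{'beta':>8s}{'R^2':>8s}{'df':>4s}{'p':>10s}")
for name, res in trends.items():
    print(f"{name:<22s}{res.beta:8.3f}{res.r_squared:8.3f}"
          f"{res.df:4d}{res.p_value:10.2g}")
print(json.dumps({
    "pharmacy_week1_pct": round(100 * weeks[0].pharmacy_share, 2),
    "pharmacy_week10_pct": round(100 * weeks[-1].pharmacy_share, 2),
}, indent=2))
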