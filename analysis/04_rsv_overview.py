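#!/usr/bin/env python
"""Relative-search-volume views: vaccine share of covid queries, myth RSV.

Two demonstrations of the RSV operations on synthetic daily series:

1. Overview ratio — 105 days of covid-query volume whose vaccine-related
   fraction ramps linearly from 10% to 50%; the daily ratio series is
   fit with OLS (df = 103).
2. Joint myth-term RSV — five myth-topic series normalized against one
   shared peak, mimicking a simultaneous multi-term trends comparison.

Writes results/rsv_myths.csv and prints the overview fit.
"""

import argparse
import datetime as dt
from pathlib import Path

import numpy as np

from vaxquery import fit_trend, rsv_normalize, share_ratio_series
from vaxquery.io import write_rsv

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

rng = np.random.default_rng(args.seed + 10_007)

# 1. vaccine share of all covid-related queries, daily
n_days = 105
start = dt.date(2020, 12, 1)
dates = [start + dt.timedelta(days=d) for d in range(n_days)]
daily_covid = 1_000_000
p = np.linspace(0.10, 0.50, n_days)
vaccine = rng.binomial(daily_covid, p)
ratio = share_ratio_series(vaccine, np.full(n_days, daily_covid))
res = fit_trend(list(zip(range(n_days), 100.0 * ratio)))
print(f"vaccine share of covid queries: {100 * ratio[0]:.1f}% -> "
      f"{100 * ratio[-1]:.1f}% over {n_days} days")
print(f"daily OLS trend: df={res.df}, R^2={res.r_squared:.2f}, "
      f"beta={res.beta:.2f} pp/day, p={res.p_value:.2g}")

# 2. joint RSV for the five myth topics (relative interest levels chosen so
# infertility- and dna-related searches dominate, the ordering the myth
# categories show)
topic_level = {
    "vaccine_infertility": 1.0,
    "vaccine_dna": 0.8,
    "vaccine_microchip": 0.35,
    "vaccine_5g": 0.25,
    "covid_from_vaccine": 0.45,
}
series = []
for label, level in topic_level.items():
    base = level * (1000 + 400 * np.sin(np.linspace(0, 3, n_days)))
    counts = rng.poisson(np.clip(base, 0, None))
    series.append((label, dates, counts.tolist()))
rsv = rsv_normalize(series)
args.out_dir.mkdir(parents=True, exist_ok=True)
write_rsv(rsv, args.out_dir / "rsv_myths.csv")
peaks = {s.label: max(s.values) for s in rsv}
print("joint myth RSV peaks (%):",
      {k: round(v, 1) for k, v in sorted(peaks.items(), key=lambda kv: -kv[1])})
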