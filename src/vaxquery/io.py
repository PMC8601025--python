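"""Readers and writers for the pipeline's tabular artifacts.

All files are UTF-8 text: query logs and classified logs as TSV, weekly
shares and RSV series as CSV, trend fits and evaluation reports as JSON.
Floats are written at full precision (repr round-trip), so
write-then-read reproduces in-memory values exactly.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .records import (
    Category,
    ClassifiedQuery,
    GoldLabel,
    QueryRecord,
    format_categories,
    parse_categories,
)
from .trends import RSVSeries, TrendResult, WeeklyCategoryShares

__all__ = [
    "read_query_log",
    "write_query_log",
    "write_classified",
    "read_classified",
    "read_gold",
    "write_gold",
    "write_weekly_shares",
    "read_weekly_shares",
    "write_trend_results",
    "write_rsv",
    "read_count_series",
    "file_sha256",
]


def read_query_log(path: str | Path) -> list[QueryRecord]:
    """Read a query log (TSV/CSV by extension) with columns date, query[, count]."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"query": str})
    missing = {"date", "query"} - set(df.columns)
    if missing:
        raise ValueError(f"query log missing columns: {sorted(missing)}")
    if "count" not in df.columns:
        df["count"] = 1
    return [
        QueryRecord(
            date=dt.date.fromisoformat(str(row.date)),
            text=str(row.query),
            count=int(row.count),
        )
        for row in df.itertuples()
    ]


def write_query_log(records: Iterable[QueryRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "query": [r.text for r in records],
            "count": [r.count for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_classified(classified: Iterable[ClassifiedQuery], path: str | Path) -> None:
    rows = []
    for cq in classified:
        rows.append(
            {
                "date": cq.record.date.isoformat(),
                "query": cq.record.text,
                "count": cq.record.count,
                "categories": format_categories(cq.categories),
                "pharmacy": int(cq.pharmacy),
                "matched_terms": ";".join(
                    f"{pat}:{cat.value}" for pat, cat in cq.matched_terms
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_classified(path: str | Path) -> list[ClassifiedQuery]:
    df = pd.read_csv(path, sep="\t", dtype={"query": str}, keep_default_na=False)
    out = []
    for row in df.itertuples():
        matched = []
        if row.matched_terms:
            for item in str(row.matched_terms).split(";"):
                pat, _, cat = item.rpartition(":")
                matched.append((pat, Category(cat)))
        out.append(
            ClassifiedQuery(
                record=QueryRecord(
                    date=dt.date.fromisoformat(str(row.date)),
                    text=str(row.query),
                    count=int(row.count),
                ),
                categories=parse_categories(str(row.categories)),
                pharmacy=bool(int(row.pharmacy)),
                matched_terms=tuple(matched),
            )
        )
    return out


def write_gold(gold: Iterable[GoldLabel], path: str | Path) -> None:
    rows = [
        {
            "date": g.date.isoformat(),
            "query": g.text,
            "categories": format_categories(g.categories),
            "pharmacy": int(g.pharmacy),
        }
        for g in gold
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gold(path: str | Path) -> list[GoldLabel]:
    df = pd.read_csv(path, sep="\t", dtype={"query": str}, keep_default_na=False)
    return [
        GoldLabel(
            date=dt.date.fromisoformat(str(row.date)),
            text=str(row.query),
            categories=parse_categories(str(row.categories)),
            pharmacy=bool(int(row.pharmacy)),
        )
        for row in df.itertuples()
    ]


def _weekly_df(weeks: Sequence[WeeklyCategoryShares]) -> pd.DataFrame:
    rows = []
    for w in weeks:
        row = {
            "week_index": w.week_index,
            "week_start": w.week_start.isoformat(),
            "total_volume": w.total_volume,
        }
        for cat in Category:
            row[cat.value] = repr(w.shares[cat])
        row["pharmacy"] = repr(w.pharmacy_share)
        rows.append(row)
    return pd.DataFrame(rows)


def write_weekly_shares(
    weeks: Sequence[WeeklyCategoryShares], path: str | Path
) -> None:
    _weekly_df(weeks).to_csv(path, index=False)


def read_weekly_shares(path: str | Path) -> list[WeeklyCategoryShares]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        WeeklyCategoryShares(
            week_index=int(row.week_index),
            week_start=dt.date.fromisoformat(str(row.week_start)),
            total_volume=int(row.total_volume),
            shares={cat: float(getattr(row, cat.value)) for cat in Category},
            pharmacy_share=float(row.pharmacy),
        )
        for row in df.itertuples()
    ]


def write_trend_results(
    results: dict[str, TrendResult], path: str | Path
) -> None:
    payload = {
        name: {
            "beta": r.beta,
            "intercept": r.intercept,
            "r_squared": r.r_squared,
            "df": r.df,
            "p_value": r.p_value,
            "n_points": r.n_points,
            "degenerate": r.degenerate,
        }
        for name, r in results.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_rsv(series: Sequence[RSVSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for ts, v in zip(s.timestamps, s.values):
            rows.append({"date": ts.isoformat(), "label": s.label, "rsv": repr(v)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_count_series(
    path: str | Path,
) -> list[tuple[str, list[dt.date], list[float]]]:
    """Read a (date, label, count) CSV into per-label series for RSV ops."""
    df = pd.read_csv(path, dtype={"label": str})
    missing = {"date", "label", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"count series missing columns: {sorted(missing)}")
    out = []
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("date")
        out.append(
            (
                str(label),
                [dt.date.fromisoformat(str(d)) for d in grp["date"]],
                [float(c) for c in grp["count"]],
            )
        )
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
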