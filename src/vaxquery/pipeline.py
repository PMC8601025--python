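"""Composite pipeline run: filter -> classify -> weekly shares -> trends -> eval.

One :func:`run_pipeline` call executes every stage on a query log and
writes all artifacts plus a machine-readable manifest (input checksums,
configuration echo, package and lexicon versions), so a run is fully
reproducible and auditable.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .classifier import classify_log, daily_topk, filter_study_log
from .evaluation import precision_recall, specific_coverage
from .io import (
    file_sha256,
    read_gold,
    read_query_log,
    write_classified,
    write_trend_results,
    write_weekly_shares,
)
from .lexicon import Lexicon, default_lexicon, load_lexicon
from .trends import fit_all_trends, weekly_shares

logger = logging.getLogger("vaxquery")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, study window, and stage flags for a composite run."""

    log_path: Path
    out_prefix: Path
    window: tuple[dt.date, dt.date]
    lexicon_path: Path | None = None
    gold_path: Path | None = None
    apply_filter: bool = True
    topk: int | None = None
    unweighted_eval: bool = False

    def __post_init__(self) -> None:
        start, end = self.window
        if start >= end:
            raise ValueError(f"study window start {start} not before end {end}")
        if not Path(self.log_path).exists():
            raise FileNotFoundError(f"query log not found: {self.log_path}")
        if self.lexicon_path is not None and not Path(self.lexicon_path).exists():
            raise FileNotFoundError(f"lexicon not found: {self.lexicon_path}")
        if self.gold_path is not None and not Path(self.gold_path).exists():
            raise FileNotFoundError(f"gold labels not found: {self.gold_path}")


def _load_lexicon(config: PipelineConfig) -> Lexicon:
    if config.lexicon_path is None:
        return default_lexicon()
    return load_lexicon(config.lexicon_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    lexicon = _load_lexicon(config)
    records = read_query_log(config.log_path)
    logger.info("loaded %d query records from %s", len(records), config.log_path)

    if config.apply_filter:
        records = filter_study_log(records, lexicon)
        logger.info("inclusion filter retained %d records", len(records))
    if config.topk is not None:
        records = daily_topk(records, config.topk)
        logger.info("daily top-%d truncation retained %d records",
                    config.topk, len(records))

    classified = classify_log(records, lexicon)
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    classified_path = Path(f"{prefix}.classified.tsv")
    write_classified(classified, classified_path)

    weeks = weekly_shares(classified, config.window)
    weekly_path = Path(f"{prefix}.weekly.csv")
    write_weekly_shares(weeks, weekly_path)
    logger.info("aggregated %d full weeks", len(weeks))

    trends = fit_all_trends(weeks)
    trends_path = Path(f"{prefix}.trends.json")
    write_trend_results(trends, trends_path)

    coverage = specific_coverage(
        classified, lexicon=lexicon, weighted=not config.unweighted_eval
    )

    manifest: dict = {
        "package_version": __version__,
        "lexicon_version": lexicon.version,
        "inputs": {"log": file_sha256(config.log_path)},
        "config": {
            "window": [config.window[0].isoformat(), config.window[1].isoformat()],
            "apply_filter": config.apply_filter,
            "topk": config.topk,
            "unweighted_eval": config.unweighted_eval,
        },
        "n_records": len(records),
        "n_weeks": len(weeks),
        "specific_coverage": coverage,
        "outputs": {},
    }
    if config.lexicon_path is not None:
        manifest["inputs"]["lexicon"] = file_sha256(config.lexicon_path)

    if config.gold_path is not None:
        gold = read_gold(config.gold_path)
        report = precision_recall(classified, gold)
        eval_path = Path(f"{prefix}.eval.json")
        eval_path.write_text(
            json.dumps(report.as_dict(), indent=2) + "\n", encoding="utf-8"
        )
        manifest["inputs"]["gold"] = file_sha256(config.gold_path)
        manifest["outputs"]["eval"] = file_sha256(eval_path)

    for name, path in (("classified", classified_path),
                       ("weekly", weekly_path), ("trends", trends_path)):
        manifest["outputs"][name] = file_sha256(path)

    manifest_path = Path(f"{prefix}.manifest.json")
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
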