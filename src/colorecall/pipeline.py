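"""End-to-end orchestration: intake → extraction → decision → worksheet.

Mirrors the three-step production workflow: documents are routed in from
the manifest, the extraction engine gates each one, and ready reports
run through the decision engine against the patient-snapshot table.
Every report lands in exactly one worksheet row; not-ready reports are
additionally routed to a review-queue file for human validation.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .decisions import Action, Decision, evaluate, load_snapshots
from .extraction import ExtractionConfig, Readiness, extract
from .intake import IntakeError, ScannedReport, load_reports
from .worksheet import WorksheetRow, build_row, summarize, write_worksheet

logger = logging.getLogger("colorecall")


@dataclass
class PipelineResult:
    rows: list[WorksheetRow]
    errors: list[IntakeError]
    batch_summaries: list[pd.DataFrame] = field(default_factory=list)

    @property
    def n_reports(self) -> int:
        return len(self.rows)

    @property
    def n_ready(self) -> int:
        return sum(1 for r in self.rows if r.readiness is Readiness.RPA_READY)

    @property
    def n_not_ready(self) -> int:
        return sum(1 for r in self.rows if r.readiness is Readiness.NOT_READY)

    @property
    def n_update(self) -> int:
        return sum(1 for r in self.rows if r.action is Action.UPDATE)

    @property
    def n_no_action(self) -> int:
        return sum(1 for r in self.rows if r.action is Action.NO_ACTION)


def process_reports(
    reports: Sequence[ScannedReport],
    snapshots: dict,
    config: Optional[ExtractionConfig] = None,
    timestamp: Optional[str] = None,
) -> list[WorksheetRow]:
    """Run extraction and decision for a batch of in-memory reports."""
    config = config or ExtractionConfig()
    timestamp = timestamp or datetime.datetime.now().isoformat(timespec="seconds")
    rows: list[WorksheetRow] = []
    for report in reports:
        extraction = extract(report, config)
        snapshot = snapshots.get(report.patient_id)
        decision: Optional[Decision] = None
        if extraction.readiness is Readiness.RPA_READY:
            decision = evaluate(extraction, report, snapshot)
        rows.append(build_row(extraction, report.patient_id, decision, snapshot, timestamp))
    return rows


def run_pipeline(
    manifest: str | Path,
    reports_dir: str | Path,
    snapshots_path: str | Path,
    out_dir: str | Path,
    config: Optional[ExtractionConfig] = None,
    batch_size: Optional[int] = None,
    timestamp: Optional[str] = None,
) -> PipelineResult:
    """Process a full manifest and write the audit artifacts.

    Writes ``worksheet.csv``, ``summary.csv`` and ``review_queue.csv``
    under ``out_dir``. Record-level intake errors are logged and
    accumulated; processing continues. ``batch_size`` emulates staged
    small-batch rollout: reports are processed in chunks with a per-batch
    summary logged and retained.
    """
    if batch_size is not None and batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or ExtractionConfig()

    reports, errors = load_reports(manifest, reports_dir)
    for err in errors:
        logger.warning("intake error for %s: %s", err.report_id, err.message)
    snapshots = load_snapshots(snapshots_path)

    rows: list[WorksheetRow] = []
    batch_summaries: list[pd.DataFrame] = []
    step = batch_size or max(len(reports), 1)
    for start in range(0, len(reports), step):
        batch = reports[start : start + step]
        batch_rows = process_reports(batch, snapshots, config, timestamp)
        rows.extend(batch_rows)
        if batch_size is not None:
            batch_summary = summarize(batch_rows)
            batch_summaries.append(batch_summary)
            logger.info(
                "batch %d: %d reports, %d ready",
                len(batch_summaries),
                len(batch_rows),
                sum(1 for r in batch_rows if r.readiness is Readiness.RPA_READY),
            )

    write_worksheet(rows, out_dir / "worksheet.csv")
    summarize(rows).to_csv(out_dir / "summary.csv", index=False)
    review = [r.report_id for r in rows if r.readiness is Readiness.NOT_READY]
    pd.DataFrame({"report_id": review}).to_csv(out_dir / "review_queue.csv", index=False)

    result = PipelineResult(rows=rows, errors=errors, batch_summaries=batch_summaries)
    logger.info(
        "processed %d reports: %d ready (%d updated, %d blocked), %d to review",
        result.n_reports,
        result.n_ready,
        result.n_update,
        result.n_no_action,
        result.n_not_ready,
    )
    return result
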