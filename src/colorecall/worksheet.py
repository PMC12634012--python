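"""Audit worksheet: one row per processed report, plus summary counts.

The worksheet is the pipeline's "input spreadsheet" analogue — the
single auditable record of what was extracted, at what confidence, and
what the decision engine did. Written as plain CSV with a frozen column
order so runs are diffable.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .decisions import Action, Decision, PatientSnapshot
from .extraction import DocType, ExtractionResult, Readiness, RecKind

WORKSHEET_COLUMNS = [
    "report_id",
    "patient_id",
    "doc_type",
    "doc_type_confidence",
    "result_date",
    "result_date_confidence",
    "rec_kind",
    "rec_low_months",
    "rec_high_months",
    "rec_explicit_date",
    "recommendation_confidence",
    "resolved_due_date",
    "readiness",
    "action",
    "exception_code",
    "new_due_date",
    "prior_due_date",
    "timestamp",
]


@dataclass(frozen=True)
class WorksheetRow:
    report_id: str
    patient_id: str
    doc_type: DocType
    doc_type_confidence: float
    result_date: Optional[datetime.date]
    result_date_confidence: float
    rec_kind: RecKind
    rec_low_months: Optional[int]
    rec_high_months: Optional[int]
    rec_explicit_date: Optional[datetime.date]
    recommendation_confidence: float
    resolved_due_date: Optional[datetime.date]
    readiness: Readiness
    action: Optional[Action]
    exception_code: Optional[str]
    new_due_date: Optional[datetime.date]
    prior_due_date: Optional[datetime.date]
    timestamp: str

    def __post_init__(self) -> None:
        if self.readiness is Readiness.NOT_READY and (
            self.action is not None or self.exception_code is not None
        ):
            raise ValueError("NOT_READY rows carry no action or exception")


def build_row(
    extraction: ExtractionResult,
    patient_id: str,
    decision: Optional[Decision],
    snapshot: Optional[PatientSnapshot],
    timestamp: str,
) -> WorksheetRow:
    """Assemble one worksheet row from the pipeline stage outputs.

    ``decision`` is None exactly for NOT_READY reports (they never reach
    the decision engine).
    """
    rec = extraction.recommendation
    return WorksheetRow(
        report_id=extraction.report_id,
        patient_id=patient_id,
        doc_type=extraction.doc_type,
        doc_type_confidence=extraction.doc_type_confidence,
        result_date=extraction.result_date,
        result_date_confidence=extraction.result_date_confidence,
        rec_kind=rec.kind,
        rec_low_months=rec.low_months,
        rec_high_months=rec.high_months,
        rec_explicit_date=rec.explicit_date,
        recommendation_confidence=extraction.recommendation_confidence,
        resolved_due_date=extraction.resolved_due_date,
        readiness=extraction.readiness,
        action=decision.action if decision is not None else None,
        exception_code=decision.exception_code if decision is not None else None,
        new_due_date=decision.new_due_date if decision is not None else None,
        prior_due_date=snapshot.current_due_date if snapshot is not None else None,
        timestamp=timestamp,
    )


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, datetime.date):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    if hasattr(value, "value"):  # enums render as their payload
        return value.value
    return str(value)


def write_worksheet(rows: Sequence[WorksheetRow], path: str | Path) -> None:
    """Write rows as CSV with the frozen column order; losslessly re-readable."""
    records = [
        {col: _cell(getattr(row, col)) for col in WORKSHEET_COLUMNS} for row in rows
    ]
    pd.DataFrame(records, columns=WORKSHEET_COLUMNS).to_csv(path, index=False)


def _opt_date(value: str) -> Optional[datetime.date]:
    return datetime.date.fromisoformat(value) if value else None


def _opt_int(value: str) -> Optional[int]:
    return int(value) if value else None


def read_worksheet(path: str | Path) -> list[WorksheetRow]:
    """Read a worksheet CSV back into typed rows (inverse of write)."""
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows: list[WorksheetRow] = []
    for r in table.itertuples(index=False):
        rows.append(
            WorksheetRow(
                report_id=r.report_id,
                patient_id=r.patient_id,
                doc_type=DocType(r.doc_type),
                doc_type_confidence=float(r.doc_type_confidence),
                result_date=_opt_date(r.result_date),
                result_date_confidence=float(r.result_date_confidence),
                rec_kind=RecKind(r.rec_kind),
                rec_low_months=_opt_int(r.rec_low_months),
                rec_high_months=_opt_int(r.rec_high_months),
                rec_explicit_date=_opt_date(r.rec_explicit_date),
                recommendation_confidence=float(r.recommendation_confidence),
                resolved_due_date=_opt_date(r.resolved_due_date),
                readiness=Readiness(r.readiness),
                action=Action(r.action) if r.action else None,
                exception_code=r.exception_code or None,
                new_due_date=_opt_date(r.new_due_date),
                prior_due_date=_opt_date(r.prior_due_date),
                timestamp=r.timestamp,
            )
        )
    return rows


def summarize(rows: Sequence[WorksheetRow]) -> pd.DataFrame:
    """Counts per (readiness, action, exception_code); rows partition exactly.

    This is the leadership-summary analogue: how many reports were ready,
    how many due dates were updated, and which rule blocked the rest.
    """
    records = [
        {
            "readiness": row.readiness.value,
            "action": row.action.value if row.action is not None else "",
            "exception_code": row.exception_code or "",
        }
        for row in rows
    ]
    if not records:
        return pd.DataFrame(columns=["readiness", "action", "exception_code", "count"])
    frame = pd.DataFrame(records)
    summary = (
        frame.groupby(["readiness", "action", "exception_code"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["readiness", "action", "exception_code"], kind="stable")
        .reset_index(drop=True)
    )
    return summary
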