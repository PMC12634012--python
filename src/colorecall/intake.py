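"""Report intake: load scanned report text files and their manifest.

Stands in for the fax / document-management routing step of the workflow:
inbound colonoscopy reports arrive as plain-text files listed in a CSV
manifest carrying the scan metadata (patient id, scan date, and the
procedure date the intake system linked to the document).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

#: Fixed manifest schema; dates are ISO-8601, blank means absent.
MANIFEST_COLUMNS = ["report_id", "patient_id", "file", "scan_date", "linked_procedure_date"]


class IntakeValidationError(ValueError):
    """A ScannedReport violated a structural invariant."""


@dataclass(frozen=True)
class ScannedReport:
    """One inbound unstructured document plus its scan metadata.

    Parameters
    ----------
    report_id, patient_id
        Opaque identifiers from the intake system (patient identity is
        never extracted from the text itself).
    raw_text
        Full document text; must be non-empty after whitespace stripping.
    scan_date
        Date the document was scanned into the record system.
    linked_procedure_date
        Procedure date the intake system attached to the document, if any.
        Used by the decision engine for order matching and the
        date-mismatch exception.
    source_label
        Free-text origin, e.g. an external clinic name.
    """

    report_id: str
    patient_id: str
    raw_text: str
    scan_date: datetime.date
    linked_procedure_date: Optional[datetime.date] = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.raw_text.strip():
            raise IntakeValidationError(f"report {self.report_id!r}: empty text")
        if (
            self.linked_procedure_date is not None
            and self.scan_date < self.linked_procedure_date
        ):
            raise IntakeValidationError(
                f"report {self.report_id!r}: scan_date {self.scan_date} precedes "
                f"linked_procedure_date {self.linked_procedure_date}"
            )


@dataclass(frozen=True)
class IntakeError:
    """A record-level problem for one manifest row (batch continues)."""

    report_id: str
    message: str


def _parse_date(value: str, what: str) -> Optional[datetime.date]:
    value = (value or "").strip()
    if not value:
        return None
    try:
        return datetime.date.fromisoformat(value)
    except ValueError as exc:
        raise ValueError(f"unparseable {what} {value!r}") from exc


def load_reports(
    manifest_path: str | Path, reports_dir: str | Path
) -> tuple[list[ScannedReport], list[IntakeError]]:
    """Load all reports listed in a manifest.

    Returns ``(reports, errors)``: one :class:`ScannedReport` per valid
    manifest row, in manifest order, plus accumulated record-level errors
    (missing file, unparseable date, invariant violation). Faxed/OCR text
    is dirty, so files are decoded as UTF-8 with replacement rather than
    rejected. An empty manifest yields an empty list, not an error.
    """
    manifest_path = Path(manifest_path)
    reports_dir = Path(reports_dir)
    table = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest {manifest_path} lacks columns: {missing}")

    reports: list[ScannedReport] = []
    errors: list[IntakeError] = []
    for row in table.itertuples(index=False):
        report_id = row.report_id
        try:
            scan_date = _parse_date(row.scan_date, "scan_date")
            if scan_date is None:
                raise ValueError("missing scan_date")
            linked = _parse_date(row.linked_procedure_date, "linked_procedure_date")
            path = reports_dir / row.file
            if not path.is_file():
                raise FileNotFoundError(f"report file not found: {row.file!r}")
            text = path.read_text(encoding="utf-8", errors="replace")
            source = getattr(row, "source_label", "")
            reports.append(
                ScannedReport(
                    report_id=report_id,
                    patient_id=row.patient_id,
                    raw_text=text,
                    scan_date=scan_date,
                    linked_procedure_date=linked,
                    source_label=source,
                )
            )
        except (ValueError, OSError, IntakeValidationError) as exc:
            errors.append(IntakeError(report_id=report_id, message=str(exc)))
    return reports, errors


def write_manifest(rows: Sequence[dict], path: str | Path) -> None:
    """Write a manifest CSV with the fixed column order."""
    frame = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS + ["source_label"])
    frame.to_csv(path, index=False)
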