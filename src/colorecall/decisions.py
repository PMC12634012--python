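"""Business-rule decision engine for health-maintenance (HM) updates.

Implements the automated-execution step of the workflow: a report that
cleared the extraction readiness gate is checked against the patient's
simulated EHR HM state. Nine business exceptions — plus a staleness guard
audited under its own label — each block the update; if none hold, the
HM colonoscopy due date is replaced by the extracted follow-up date.

Two independent routes are provided on purpose:

* :func:`evaluate` — the production path: a fixed-precedence chain that
  stops at the first blocking rule.
* :func:`audit_predicates` — a flat restatement of every rule, each
  evaluated unconditionally with its own arithmetic (hand-rolled
  calendar-clamp month addition rather than dateutil). The synthetic
  corpus generator and the test suite use it as a brute-force oracle.
"""

from __future__ import annotations

import calendar
import datetime
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from dateutil.relativedelta import relativedelta

from .extraction import ExtractionResult, Readiness
from .intake import ScannedReport


class Action(str, Enum):
    UPDATE = "UPDATE"
    NO_ACTION = "NO_ACTION"


#: Blocking-rule codes. E1–E9 are the numbered business exceptions; STALE is
#: the report-older-than-last-documented-colonoscopy guard, which appears in
#: operational tallies under its own label rather than a number.
EXCEPTION_DESCRIPTIONS: dict[str, str] = {
    "E1": "proposed follow-up not earlier than the existing HM due date",
    "E2": "patient has a patient-specific HM frequency modifier",
    "E3": "HM due date manually assigned after the scanned procedure date",
    "E4": "proposed follow-up is more than 10 years after the result date",
    "E5": "follow-up date cannot be assessed from the worksheet",
    "E6": "linked procedure date does not match the document's result date",
    "E7": "colonoscopy screening topic not assigned to the patient",
    "E8": "patient not found",
    "E9": "no matching colonoscopy order",
    "STALE": "a more recent colonoscopy is already documented",
}

#: Fixed evaluation precedence: identity/structural failures first, then
#: data quality, then clinical guards.
PRECEDENCE = ("E8", "E7", "E9", "E5", "E6", "STALE", "E2", "E3", "E4", "E1")

HORIZON_MONTHS = 120  # the 10-year HM default interval


class ContractViolation(RuntimeError):
    """An operation was called outside its stated precondition."""


@dataclass(frozen=True)
class Order:
    order_id: str
    order_date: datetime.date
    outstanding: bool


@dataclass(frozen=True)
class PatientSnapshot:
    """Simulated EHR HM state for one patient."""

    patient_id: str
    age_years: int
    hm_topic_assigned: bool = True
    current_due_date: Optional[datetime.date] = None
    default_interval_months: int = HORIZON_MONTHS
    frequency_modifier: bool = False
    manual_assignment_date: Optional[datetime.date] = None
    last_documented_colonoscopy_date: Optional[datetime.date] = None
    orders: tuple[Order, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.age_years <= 120:
            raise ValueError(f"implausible age {self.age_years}")
        if self.manual_assignment_date is not None and self.current_due_date is None:
            raise ValueError("manual_assignment_date requires a current_due_date")


@dataclass(frozen=True)
class Decision:
    report_id: str
    action: Action
    exception_code: Optional[str] = None
    new_due_date: Optional[datetime.date] = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.action is Action.UPDATE:
            if self.exception_code is not None or self.new_due_date is None:
                raise ValueError("UPDATE requires a new due date and no exception code")
        else:
            if self.exception_code is None:
                raise ValueError("NO_ACTION requires an exception code")
            if self.exception_code not in EXCEPTION_DESCRIPTIONS:
                raise ValueError(f"unknown exception code {self.exception_code!r}")


def match_order(report: ScannedReport, snapshot: PatientSnapshot) -> Optional[str]:
    """Most recent outstanding order placed on or before the linked procedure date.

    A report can only be attached to an order that already existed when
    the procedure happened; absent any such order the update is blocked
    (E9).
    """
    if report.linked_procedure_date is None:
        return None
    best: Optional[Order] = None
    for order in snapshot.orders:
        if not order.outstanding or order.order_date > report.linked_procedure_date:
            continue
        if best is None or order.order_date > best.order_date:
            best = order
    return best.order_id if best is not None else None


def evaluate(
    extraction: ExtractionResult,
    report: ScannedReport,
    snapshot: Optional[PatientSnapshot],
) -> Decision:
    """Apply the blocking rules in precedence order; update only if none hold.

    Only reports gated RPA_READY may reach the engine; calling with a
    NOT_READY extraction raises :class:`ContractViolation`. The snapshot
    is never mutated.
    """
    if extraction.readiness is not Readiness.RPA_READY:
        raise ContractViolation("evaluate() requires an RPA_READY extraction")

    def blocked(code: str) -> Decision:
        return Decision(
            report_id=extraction.report_id,
            action=Action.NO_ACTION,
            exception_code=code,
            rationale=EXCEPTION_DESCRIPTIONS[code],
        )

    if snapshot is None:
        return blocked("E8")
    if not snapshot.hm_topic_assigned:
        return blocked("E7")
    if match_order(report, snapshot) is None:
        return blocked("E9")
    proposed = extraction.resolved_due_date
    result_date = extraction.result_date
    if proposed is None or result_date is None:  # defensive; gate guarantees both
        return blocked("E5")
    if report.linked_procedure_date != result_date:
        return blocked("E6")
    last = snapshot.last_documented_colonoscopy_date
    if last is not None and result_date < last:
        return blocked("STALE")
    if snapshot.frequency_modifier:
        return blocked("E2")
    if (
        snapshot.manual_assignment_date is not None
        and report.linked_procedure_date is not None
        and snapshot.manual_assignment_date > report.linked_procedure_date
    ):
        return blocked("E3")
    if proposed > result_date + relativedelta(months=HORIZON_MONTHS):
        return blocked("E4")
    if snapshot.current_due_date is not None and proposed >= snapshot.current_due_date:
        return blocked("E1")
    return Decision(
        report_id=extraction.report_id,
        action=Action.UPDATE,
        new_due_date=proposed,
        rationale="no business exception; HM due date updated",
    )


def apply_update(snapshot: PatientSnapshot, decision: Decision) -> PatientSnapshot:
    """Return a new snapshot with the due date replaced; input untouched."""
    if decision.action is not Action.UPDATE:
        raise ContractViolation("apply_update() requires an UPDATE decision")
    return replace(snapshot, current_due_date=decision.new_due_date)


# --------------------------------------------------------------------------
# brute-force audit oracle
# --------------------------------------------------------------------------


def _add_months_clamped(day: datetime.date, months: int) -> datetime.date:
    """Month addition with end-of-month clamping, no external library."""
    month_index = day.year * 12 + (day.month - 1) + months
    year, month = divmod(month_index, 12)
    month += 1
    last = calendar.monthrange(year, month)[1]
    return datetime.date(year, month, min(day.day, last))


def audit_predicates(
    extraction: ExtractionResult,
    report: ScannedReport,
    snapshot: Optional[PatientSnapshot],
) -> dict[str, bool]:
    """Evaluate every blocking rule independently and unconditionally.

    Written as a flat transcription of the rule list, with its own order
    scan and month arithmetic, so it can serve as an oracle for
    :func:`evaluate`: the engine must update exactly when no predicate
    here is true, and must report the first true predicate in
    :data:`PRECEDENCE` otherwise.
    """
    proposed = extraction.resolved_due_date
    result_date = extraction.result_date
    linked = report.linked_procedure_date

    flags = dict.fromkeys(PRECEDENCE, False)
    flags["E8"] = snapshot is None
    if snapshot is None:
        return flags
    flags["E7"] = not snapshot.hm_topic_assigned
    has_order = False
    if linked is not None:
        for order in snapshot.orders:
            if order.outstanding and order.order_date <= linked:
                has_order = True
    flags["E9"] = not has_order
    flags["E5"] = proposed is None or result_date is None
    if not flags["E5"]:
        flags["E6"] = linked != result_date
        flags["STALE"] = (
            snapshot.last_documented_colonoscopy_date is not None
            and result_date < snapshot.last_documented_colonoscopy_date
        )
        flags["E4"] = proposed > _add_months_clamped(result_date, HORIZON_MONTHS)
        flags["E1"] = (
            snapshot.current_due_date is not None and proposed >= snapshot.current_due_date
        )
    flags["E2"] = snapshot.frequency_modifier
    flags["E3"] = (
        snapshot.manual_assignment_date is not None
        and linked is not None
        and snapshot.manual_assignment_date > linked
    )
    return flags


def first_blocking_code(flags: Mapping[str, bool]) -> Optional[str]:
    """The highest-precedence true predicate, or None if all are false."""
    for code in PRECEDENCE:
        if flags[code]:
            return code
    return None


# --------------------------------------------------------------------------
# snapshot table I/O
# --------------------------------------------------------------------------

SNAPSHOT_COLUMNS = [
    "patient_id",
    "age_years",
    "hm_topic_assigned",
    "current_due_date",
    "default_interval_months",
    "frequency_modifier",
    "manual_assignment_date",
    "last_documented_colonoscopy_date",
    "orders",
]


def _fmt_date(value: Optional[datetime.date]) -> str:
    return value.isoformat() if value is not None else ""


def _parse_opt_date(value: str) -> Optional[datetime.date]:
    value = (value or "").strip()
    return datetime.date.fromisoformat(value) if value else None


def _serialize_orders(orders: Sequence[Order]) -> str:
    return ";".join(
        f"{o.order_id}:{o.order_date.isoformat()}:{int(o.outstanding)}" for o in orders
    )


def _parse_orders(raw: str) -> tuple[Order, ...]:
    raw = (raw or "").strip()
    if not raw:
        return ()
    orders = []
    for chunk in raw.split(";"):
        order_id, date_str, flag = chunk.split(":")
        orders.append(
            Order(
                order_id=order_id,
                order_date=datetime.date.fromisoformat(date_str),
                outstanding=bool(int(flag)),
            )
        )
    return tuple(orders)


def write_snapshots(snapshots: Sequence[PatientSnapshot], path: str | Path) -> None:
    """Write the patient-snapshot table as CSV (documented schema)."""
    rows = [
        {
            "patient_id": s.patient_id,
            "age_years": s.age_years,
            "hm_topic_assigned": int(s.hm_topic_assigned),
            "current_due_date": _fmt_date(s.current_due_date),
            "default_interval_months": s.default_interval_months,
            "frequency_modifier": int(s.frequency_modifier),
            "manual_assignment_date": _fmt_date(s.manual_assignment_date),
            "last_documented_colonoscopy_date": _fmt_date(s.last_documented_colonoscopy_date),
            "orders": _serialize_orders(s.orders),
        }
        for s in snapshots
    ]
    pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS).to_csv(path, index=False)


def load_snapshots(path: str | Path) -> dict[str, PatientSnapshot]:
    """Load the snapshot table into a patient_id → snapshot mapping."""
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, PatientSnapshot] = {}
    for row in table.itertuples(index=False):
        snapshot = PatientSnapshot(
            patient_id=row.patient_id,
            age_years=int(row.age_years),
            hm_topic_assigned=bool(int(row.hm_topic_assigned)),
            current_due_date=_parse_opt_date(row.current_due_date),
            default_interval_months=int(row.default_interval_months),
            frequency_modifier=bool(int(row.frequency_modifier)),
            manual_assignment_date=_parse_opt_date(row.manual_assignment_date),
            last_documented_colonoscopy_date=_parse_opt_date(
                row.last_documented_colonoscopy_date
            ),
            orders=_parse_orders(row.orders),
        )
        out[snapshot.patient_id] = snapshot
    return out
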