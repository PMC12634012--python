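"""Shared test helpers: an independent brute-force decision oracle and a
randomized case generator for snapshot/extraction pairs.

The oracle is a deliberate third implementation of the blocking rules —
written directly from the rule list, independent of both the engine's
precedence chain and the package's audit transcription — so engine/oracle
agreement is a meaningful check.
"""

from __future__ import annotations

import datetime

import numpy as np
from dateutil.relativedelta import relativedelta

from colorecall.decisions import Order, PatientSnapshot
from colorecall.extraction import (
    DocType,
    ExtractionResult,
    FollowUpRecommendation,
    Readiness,
    RecKind,
)
from colorecall.intake import ScannedReport

RULE_ORDER = ("E8", "E7", "E9", "E5", "E6", "STALE", "E2", "E3", "E4", "E1")


def oracle_blocking_code(extraction, report, snapshot):
    """All blocking rules, checked flatly; returns the first per precedence."""
    hits = set()
    if snapshot is None:
        hits.add("E8")
    else:
        if not snapshot.hm_topic_assigned:
            hits.add("E7")
        linked = report.linked_procedure_date
        if not any(
            o.outstanding and linked is not None and o.order_date <= linked
            for o in snapshot.orders
        ):
            hits.add("E9")
        if extraction.resolved_due_date is None or extraction.result_date is None:
            hits.add("E5")
        else:
            if linked != extraction.result_date:
                hits.add("E6")
            last = snapshot.last_documented_colonoscopy_date
            if last is not None and extraction.result_date < last:
                hits.add("STALE")
            if extraction.resolved_due_date > extraction.result_date + relativedelta(
                months=120
            ):
                hits.add("E4")
            if (
                snapshot.current_due_date is not None
                and extraction.resolved_due_date >= snapshot.current_due_date
            ):
                hits.add("E1")
        if snapshot.frequency_modifier:
            hits.add("E2")
        if (
            snapshot.manual_assignment_date is not None
            and linked is not None
            and snapshot.manual_assignment_date > linked
        ):
            hits.add("E3")
    return next((c for c in RULE_ORDER if c in hits), None)


def _maybe(rng, p):
    return rng.random() < p


def random_ready_case(rng: np.random.Generator, index: int = 0):
    """A random RPA_READY extraction + report + snapshot(/None) triple.

    Exercises every rule: linked-date mismatches, absent snapshots,
    adversarial manual-assignment dates, long horizons, stale reports.
    """
    base = datetime.date(2022, 1, 1)
    result_date = base + datetime.timedelta(days=int(rng.integers(0, 1200)))
    if _maybe(rng, 0.12):
        linked = None
    elif _maybe(rng, 0.2):
        linked = result_date + datetime.timedelta(days=int(rng.integers(-20, 21)))
    else:
        linked = result_date
    scan_base = max(result_date, linked or result_date)
    report = ScannedReport(
        report_id=f"R{index}",
        patient_id=f"P{index}",
        raw_text="colonoscopy report",
        scan_date=scan_base + datetime.timedelta(days=int(rng.integers(1, 30))),
        linked_procedure_date=linked,
    )
    months = int(rng.integers(1, 200))
    rec = FollowUpRecommendation(kind=RecKind.INTERVAL, low_months=months, high_months=months)
    resolved = result_date + relativedelta(months=months)
    extraction = ExtractionResult(
        report_id=report.report_id,
        doc_type=DocType.COLONOSCOPY,
        doc_type_confidence=0.9,
        result_date=result_date,
        result_date_confidence=0.9,
        recommendation=rec,
        recommendation_confidence=0.9,
        resolved_due_date=resolved,
        readiness=Readiness.RPA_READY,
    )
    if _maybe(rng, 0.08):
        return extraction, report, None

    current_due = None
    if _maybe(rng, 0.7):
        current_due = resolved + datetime.timedelta(days=int(rng.integers(-400, 400)))
    manual = None
    if current_due is not None and _maybe(rng, 0.3):
        anchor = linked or result_date
        manual = anchor + datetime.timedelta(days=int(rng.integers(-90, 90)))
    last_doc = None
    if _maybe(rng, 0.5):
        last_doc = result_date + datetime.timedelta(days=int(rng.integers(-900, 300)))
    orders = []
    for j in range(int(rng.integers(0, 3))):
        anchor = linked or result_date
        orders.append(
            Order(
                order_id=f"O{index}-{j}",
                order_date=anchor + datetime.timedelta(days=int(rng.integers(-120, 40))),
                outstanding=bool(rng.integers(0, 2)),
            )
        )
    snapshot = PatientSnapshot(
        patient_id=report.patient_id,
        age_years=int(rng.integers(30, 95)),
        hm_topic_assigned=_maybe(rng, 0.85),
        current_due_date=current_due,
        frequency_modifier=_maybe(rng, 0.15),
        manual_assignment_date=manual,
        last_documented_colonoscopy_date=last_doc,
        orders=tuple(orders),
    )
    return extraction, report, snapshot
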