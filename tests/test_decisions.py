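import datetime
from dataclasses import replace

import numpy as np
import pytest
from _cases import oracle_blocking_code, random_ready_case
from hypothesis import given, settings
from hypothesis import strategies as st

from colorecall.decisions import (
    Action,
    ContractViolation,
    Order,
    PatientSnapshot,
    apply_update,
    audit_predicates,
    evaluate,
    first_blocking_code,
    load_snapshots,
    match_order,
    write_snapshots,
)
from colorecall.extraction import (
    DocType,
    ExtractionResult,
    FollowUpRecommendation,
    Readiness,
    RecKind,
)
from colorecall.intake import ScannedReport

D = datetime.date


def make_extraction(result_date, resolved, readiness=Readiness.RPA_READY):
    rec = FollowUpRecommendation(kind=RecKind.EXPLICIT_DATE, explicit_date=resolved)
    return ExtractionResult(
        report_id="r1",
        doc_type=DocType.COLONOSCOPY,
        doc_type_confidence=0.9,
        result_date=result_date,
        result_date_confidence=0.9,
        recommendation=rec,
        recommendation_confidence=0.9,
        resolved_due_date=resolved,
        readiness=readiness,
    )


def make_report(linked, scan=None):
    return ScannedReport(
        report_id="r1",
        patient_id="p1",
        raw_text="colonoscopy report",
        scan_date=scan or (linked or D(2023, 3, 1)) + datetime.timedelta(days=10),
        linked_procedure_date=linked,
    )


def clean_snapshot(result_date=D(2023, 1, 15), due=D(2033, 1, 15)):
    return PatientSnapshot(
        patient_id="p1",
        age_years=60,
        hm_topic_assigned=True,
        current_due_date=due,
        orders=(Order("o1", result_date - datetime.timedelta(days=60), True),),
    )


def test_follow_up_beyond_ten_years_is_blocked():
    extraction = make_extraction(D(2023, 3, 1), D(2036, 3, 1))  # 156 months out
    decision = evaluate(extraction, make_report(D(2023, 3, 1)), clean_snapshot(D(2023, 3, 1)))
    assert decision.action is Action.NO_ACTION and decision.exception_code == "E4"


def test_exactly_ten_years_is_allowed():
    extraction = make_extraction(D(2023, 3, 1), D(2033, 3, 1))
    decision = evaluate(
        extraction, make_report(D(2023, 3, 1)), clean_snapshot(D(2023, 3, 1), due=D(2034, 1, 1))
    )
    assert decision.action is Action.UPDATE


def test_frequency_modifier_blocks_update():
    snapshot = replace(clean_snapshot(), frequency_modifier=True)
    extraction = make_extraction(D(2023, 1, 15), D(2026, 1, 15))
    decision = evaluate(extraction, make_report(D(2023, 1, 15)), snapshot)
    assert decision.exception_code == "E2"


def test_clean_snapshot_updates_to_extracted_due_date():
    extraction = make_extraction(D(2023, 1, 15), D(2026, 1, 15))
    report = make_report(D(2023, 1, 15))
    snapshot = clean_snapshot()
    # every blocking predicate is false by the brute-force oracle
    assert oracle_blocking_code(extraction, report, snapshot) is None
    decision = evaluate(extraction, report, snapshot)
    assert decision.action is Action.UPDATE and decision.new_due_date == D(2026, 1, 15)


def test_existing_earlier_due_date_blocks_update():
    snapshot = clean_snapshot(due=D(2025, 6, 1))
    extraction = make_extraction(D(2023, 1, 15), D(2026, 1, 15))
    decision = evaluate(extraction, make_report(D(2023, 1, 15)), snapshot)
    assert decision.exception_code == "E1"


def test_equal_due_date_is_a_suppressed_noop_update():
    snapshot = clean_snapshot(due=D(2026, 1, 15))
    extraction = make_extraction(D(2023, 1, 15), D(2026, 1, 15))
    assert evaluate(extraction, make_report(D(2023, 1, 15)), snapshot).exception_code == "E1"


def test_absent_snapshot_is_patient_not_found():
    extraction = make_extraction(D(2023, 1, 15), D(2026, 1, 15))
    assert evaluate(extraction, make_report(D(2023, 1, 15)), None).exception_code == "E8"


def test_stale_report_is_blocked_under_its_own_label():
    snapshot = replace(
        clean_snapshot(), last_documented_colonoscopy_date=D(2023, 6, 1)
    )
    extraction = make_extraction(D(2023, 1, 15), D(2026, 1, 15))
    decision = evaluate(extraction, make_report(D(2023, 1, 15)), snapshot)
    assert decision.exception_code == "STALE"


def test_not_ready_extraction_violates_the_contract():
    rec = FollowUpRecommendation(kind=RecKind.NONE)
    extraction = ExtractionResult(
        report_id="r1", doc_type=DocType.OTHER, doc_type_confidence=0.0,
        result_date=None, result_date_confidence=0.0, recommendation=rec,
        recommendation_confidence=0.0, resolved_due_date=None,
        readiness=Readiness.NOT_READY,
    )
    with pytest.raises(ContractViolation):
        evaluate(extraction, make_report(D(2023, 1, 15)), clean_snapshot())


# ----------------------------- order matching -------------------------------


def test_single_outstanding_order_before_procedure_matches():
    snapshot = replace(clean_snapshot(), orders=(Order("o1", D(2022, 11, 1), True),))
    assert match_order(make_report(D(2023, 1, 15)), snapshot) == "o1"


def test_no_orders_matches_nothing():
    snapshot = replace(clean_snapshot(), orders=())
    assert match_order(make_report(D(2023, 1, 15)), snapshot) is None


def test_most_recent_qualifying_order_wins():
    snapshot = replace(
        clean_snapshot(),
        orders=(Order("o1", D(2022, 11, 1), True), Order("o2", D(2022, 12, 15), True)),
    )
    assert match_order(make_report(D(2023, 1, 15)), snapshot) == "o2"


def test_order_after_procedure_or_closed_does_not_qualify():
    snapshot = replace(
        clean_snapshot(),
        orders=(Order("o1", D(2023, 2, 1), True), Order("o2", D(2022, 12, 1), False)),
    )
    assert match_order(make_report(D(2023, 1, 15)), snapshot) is None


# ----------------------------- snapshot update ------------------------------


def test_apply_update_replaces_due_date_without_mutation():
    snapshot = clean_snapshot(due=D(2033, 1, 15))
    extraction = make_extraction(D(2023, 1, 15), D(2026, 1, 15))
    decision = evaluate(extraction, make_report(D(2023, 1, 15)), snapshot)
    updated = apply_update(snapshot, decision)
    assert updated.current_due_date == D(2026, 1, 15)
    assert snapshot.current_due_date == D(2033, 1, 15)
    assert apply_update(updated, decision) == updated  # idempotent
    blocked = evaluate(extraction, make_report(D(2023, 1, 15)), None)
    with pytest.raises(ContractViolation):
        apply_update(snapshot, blocked)


# ----------------------------- oracle equivalence ---------------------------


def test_engine_matches_brute_force_oracle_on_randomized_cases():
    rng = np.random.default_rng(2024)
    for i in range(2000):
        extraction, report, snapshot = random_ready_case(rng, i)
        expected = oracle_blocking_code(extraction, report, snapshot)
        decision = evaluate(extraction, report, snapshot)
        if expected is None:
            assert decision.action is Action.UPDATE, (i, decision)
        else:
            assert decision.action is Action.NO_ACTION
            assert decision.exception_code == expected, (i, decision.exception_code, expected)
        # the package's own audit transcription agrees too
        assert first_blocking_code(audit_predicates(extraction, report, snapshot)) == expected


def test_evaluate_is_pure():
    rng = np.random.default_rng(7)
    extraction, report, snapshot = random_ready_case(rng)
    assert evaluate(extraction, report, snapshot) == evaluate(extraction, report, snapshot)


def test_update_is_never_later_than_an_existing_due_date():
    rng = np.random.default_rng(99)
    seen = 0
    for i in range(3000):
        extraction, report, snapshot = random_ready_case(rng, i)
        decision = evaluate(extraction, report, snapshot)
        if decision.action is Action.UPDATE and snapshot.current_due_date is not None:
            seen += 1
            assert decision.new_due_date < snapshot.current_due_date
    assert seen > 0


@settings(derandomize=True, max_examples=150, deadline=None)
@given(offset=st.integers(1, 2000), due_shift=st.integers(-1500, 1500))
def test_manual_entry_after_procedure_is_never_overridden(offset, due_shift):
    """The non-override constraint: a clinician's later manual assignment wins."""
    linked = D(2023, 1, 15)
    snapshot = replace(
        clean_snapshot(),
        current_due_date=D(2026, 1, 15) + datetime.timedelta(days=due_shift),
        manual_assignment_date=linked + datetime.timedelta(days=offset),
    )
    extraction = make_extraction(linked, D(2026, 1, 15))
    decision = evaluate(extraction, make_report(linked), snapshot)
    assert decision.action is Action.NO_ACTION


# ----------------------------- snapshot table I/O ---------------------------


def test_snapshot_table_round_trips(tmp_path):
    snapshots = [
        clean_snapshot(),
        replace(clean_snapshot(), patient_id="p2", frequency_modifier=True,
                manual_assignment_date=D(2023, 5, 1)),
        PatientSnapshot(patient_id="p3", age_years=80, hm_topic_assigned=False),
    ]
    path = tmp_path / "snapshots.csv"
    write_snapshots(snapshots, path)
    loaded = load_snapshots(path)
    assert loaded == {s.patient_id: s for s in snapshots}
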