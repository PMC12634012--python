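import datetime
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colorecall.extraction import (
    CONF_FALLBACK_DATE,
    DocType,
    ExtractionConfig,
    ExtractionResult,
    FollowUpRecommendation,
    Readiness,
    RecKind,
    assess_readiness,
    classify_document,
    extract_follow_up,
    extract_result_date,
    resolve_due_date,
)

CFG = ExtractionConfig()


# ----------------------------- classification -----------------------------


def test_procedure_vocabulary_classifies_as_colonoscopy():
    text = "The cecum was reached. Withdrawal was slow. A polypectomy was performed."
    doc_type, conf = classify_document(text, CFG)
    # oracle: 3 distinct procedure terms, 0 histology terms
    assert doc_type is DocType.COLONOSCOPY
    assert conf == pytest.approx((3 / 3) * min(1.0, 3 / 3))


def test_histology_vocabulary_classifies_as_pathology():
    text = (
        "Specimen received in formalin. Microscopic description: "
        "tubular adenoma fragments."
    )
    doc_type, conf = classify_document(text, CFG)
    # oracle: 4 distinct histology terms (specimen, formalin, microscopic, adenoma)
    assert doc_type is DocType.PATHOLOGY
    assert conf == pytest.approx((4 / 4) * min(1.0, 4 / 3))


def test_zero_lexicon_evidence_yields_other_with_zero_confidence():
    doc_type, conf = classify_document("lorem ipsum dolor sit amet", CFG)
    assert doc_type is DocType.OTHER and conf == 0.0


# ----------------------------- result date --------------------------------


def test_labeled_procedure_date_extracted():
    date, conf = extract_result_date("Procedure date: 01/15/2023", CFG)
    assert date == datetime.date(2023, 1, 15) and conf > 0.9


def test_no_date_tokens_yields_absent_with_zero_confidence():
    assert extract_result_date("no dates here at all", CFG) == (None, 0.0)


def test_labeled_context_outranks_unlabeled_date():
    text = "Date of procedure: March 3, 2022\nReport printed 03/10/2022"
    date, conf = extract_result_date(text, CFG)
    assert date == datetime.date(2022, 3, 3) and conf > 0.9


def test_conflicting_labeled_dates_decrement_confidence():
    text = "Procedure date: 01/15/2023\nExam date: 01/16/2023"
    date, conf = extract_result_date(text, CFG)
    assert date == datetime.date(2023, 1, 15)
    assert conf == pytest.approx(0.80)


def test_unlabeled_letterhead_date_scores_below_the_gate():
    date, conf = extract_result_date("Letter of 06/02/2023 regarding your patient", CFG)
    assert date == datetime.date(2023, 6, 2)
    assert conf == CONF_FALLBACK_DATE < CFG.readiness_threshold


# ----------------------------- follow-up grammar ---------------------------


@pytest.mark.parametrize(
    "text, kind, low, high",
    [
        ("Recommend repeat colonoscopy in 5 years.", RecKind.INTERVAL, 60, 60),
        ("return in 3‐5 y", RecKind.RANGE, 36, 60),  # hyphen variant U+2010
        ("The patient should return in 3 to 5 years.", RecKind.RANGE, 36, 60),
        ("Plan: follow-up colonoscopy in 36 months.", RecKind.INTERVAL, 36, 36),
        ("We recommend a repeat exam within 10 yr.", RecKind.INTERVAL, 120, 120),
    ],
)
def test_interval_and_range_phrases_parse_to_months(text, kind, low, high):
    rec, conf = extract_follow_up(text, CFG)
    assert rec.kind is kind
    assert (rec.low_months, rec.high_months) == (low, high)
    assert conf > CFG.readiness_threshold


def test_explicit_date_after_follow_up_cue():
    rec, conf = extract_follow_up("The next colonoscopy is due on June 1, 2030.", CFG)
    assert rec.kind is RecKind.EXPLICIT_DATE
    assert rec.explicit_date == datetime.date(2030, 6, 1)
    assert conf > CFG.readiness_threshold


def test_negation_maps_to_none():
    rec, conf = extract_follow_up("No further surveillance colonoscopy is indicated.", CFG)
    assert rec.kind is RecKind.NONE


def test_absence_of_cue_yields_none_with_zero_confidence():
    rec, conf = extract_follow_up("The bowel prep was adequate throughout.", CFG)
    assert rec.kind is RecKind.NONE and conf == 0.0


def test_phrase_without_recommendation_cue_scores_below_gate():
    rec, conf = extract_follow_up("The patient will come back in 5 years.", CFG)
    assert rec.kind is RecKind.INTERVAL and rec.low_months == 60
    assert conf < CFG.readiness_threshold


def test_statement_nearest_cue_wins_and_tie_breaks_to_earlier_date():
    text = (
        "Previously advised in 10 years. "
        "Recommendation: repeat colonoscopy in 3 years."
    )
    rec, conf = extract_follow_up(text, CFG)
    assert rec.low_months == 36


def test_extraction_is_deterministic():
    text = "Recommend repeat colonoscopy in 5 years. Procedure date: 01/15/2023."
    assert extract_follow_up(text, CFG) == extract_follow_up(text, CFG)
    assert extract_result_date(text, CFG) == extract_result_date(text, CFG)


# ----------------------------- due-date resolution --------------------------


def test_range_resolves_to_the_earlier_bound():
    rec = FollowUpRecommendation(kind=RecKind.RANGE, low_months=36, high_months=60)
    assert resolve_due_date(rec, datetime.date(2023, 1, 15)) == datetime.date(2026, 1, 15)


def test_none_resolves_to_absent():
    assert resolve_due_date(FollowUpRecommendation(kind=RecKind.NONE), datetime.date(2023, 1, 1)) is None


def test_month_addition_clamps_to_month_end():
    rec = FollowUpRecommendation(kind=RecKind.INTERVAL, low_months=120, high_months=120)
    assert resolve_due_date(rec, datetime.date(2020, 2, 29)) == datetime.date(2030, 2, 28)


def test_resolution_translation_equivariant_over_a_year_of_start_dates():
    # brute force: shifting the result date by whole months shifts the output
    # by the same months, up to end-of-month clamping
    rec = FollowUpRecommendation(kind=RecKind.INTERVAL, low_months=60, high_months=60)
    for day in range(1, 366):
        start = datetime.date(2023, 1, 1) + datetime.timedelta(days=day - 1)
        due = resolve_due_date(rec, start)
        months = (due.year - start.year) * 12 + (due.month - start.month)
        assert months == 60
        assert due.day <= start.day  # only clamping may shrink the day


def test_malformed_nonpositive_interval_rejected():
    with pytest.raises(ValueError):
        FollowUpRecommendation(kind=RecKind.INTERVAL, low_months=0, high_months=0)


# ----------------------------- readiness gate -------------------------------


def _result(date_conf, rec_conf, kind=RecKind.INTERVAL):
    rec = (
        FollowUpRecommendation(kind=RecKind.NONE)
        if kind is RecKind.NONE
        else FollowUpRecommendation(kind=kind, low_months=60, high_months=60)
    )
    has_rec = kind is not RecKind.NONE
    return ExtractionResult(
        report_id="r",
        doc_type=DocType.COLONOSCOPY,
        doc_type_confidence=0.9,
        result_date=datetime.date(2023, 1, 15),
        result_date_confidence=date_conf,
        recommendation=rec,
        recommendation_confidence=rec_conf,
        resolved_due_date=datetime.date(2028, 1, 15) if has_rec else None,
        readiness=Readiness.NOT_READY,
    )


def test_gate_is_strict_at_the_seventy_percent_boundary():
    assert assess_readiness(_result(0.90, 0.71), CFG) is Readiness.RPA_READY
    assert assess_readiness(_result(0.90, 0.70), CFG) is Readiness.NOT_READY
    assert assess_readiness(_result(0.70, 0.90), CFG) is Readiness.NOT_READY


def test_missing_recommendation_is_never_ready():
    assert assess_readiness(_result(0.99, 0.99, kind=RecKind.NONE), CFG) is Readiness.NOT_READY


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    date_conf=st.floats(0, 1),
    rec_conf=st.floats(0, 1),
    low=st.floats(0, 1),
    high=st.floats(0, 1),
)
def test_raising_the_threshold_never_promotes_a_report(date_conf, rec_conf, low, high):
    low, high = min(low, high), max(low, high)
    extraction = _result(date_conf, rec_conf)
    ready_low = assess_readiness(extraction, replace_threshold(low))
    ready_high = assess_readiness(extraction, replace_threshold(high))
    if ready_high is Readiness.RPA_READY:
        assert ready_low is Readiness.RPA_READY


def replace_threshold(value):
    return ExtractionConfig(readiness_threshold=value)
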