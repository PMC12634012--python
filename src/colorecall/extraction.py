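"""Deterministic extraction engine for colonoscopy report text.

Replaces the learned document-processing model of the production workflow
with an auditable pattern grammar: document-type classification from
keyword lexicons, result-date extraction from labeled date contexts,
follow-up recommendation parsing (fixed interval, range, explicit date,
or negation), and a heuristic confidence score that feeds the same
readiness gate the production system used — a report is "RPA ready" only
when both required fields clear a strictly-greater-than 0.70 confidence
threshold.

All behavior is a pure function of (text, config); there is no randomness
anywhere in this module.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import yaml
from dateutil.relativedelta import relativedelta

# --------------------------------------------------------------------------
# enums and value types
# --------------------------------------------------------------------------


class DocType(str, Enum):
    COLONOSCOPY = "COLONOSCOPY"
    PATHOLOGY = "PATHOLOGY"
    OTHER = "OTHER"


class RecKind(str, Enum):
    INTERVAL = "INTERVAL"
    RANGE = "RANGE"
    EXPLICIT_DATE = "EXPLICIT_DATE"
    NONE = "NONE"


class Readiness(str, Enum):
    RPA_READY = "RPA_READY"
    NOT_READY = "NOT_READY"


@dataclass(frozen=True)
class FollowUpRecommendation:
    """A parsed follow-up statement, normalized to months internally.

    Intervals and ranges are stored in months (``years × 12``) so the
    10-year horizon rule compares a single unit. ``source_span`` is the
    character span of the matched phrase in the raw text.
    """

    kind: RecKind
    low_months: Optional[int] = None
    high_months: Optional[int] = None
    explicit_date: Optional[datetime.date] = None
    source_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        k = self.kind
        if k is RecKind.RANGE:
            if not (self.low_months and self.high_months and self.low_months < self.high_months):
                raise ValueError("RANGE requires 0 < low_months < high_months")
        elif k is RecKind.INTERVAL:
            if not (self.low_months and self.low_months > 0 and self.low_months == self.high_months):
                raise ValueError("INTERVAL requires low_months == high_months > 0")
        elif k is RecKind.EXPLICIT_DATE:
            if self.explicit_date is None:
                raise ValueError("EXPLICIT_DATE requires explicit_date")
        elif k is RecKind.NONE:
            if any(v is not None for v in (self.low_months, self.high_months, self.explicit_date)):
                raise ValueError("NONE carries no value fields")


NO_RECOMMENDATION = FollowUpRecommendation(kind=RecKind.NONE)


@dataclass(frozen=True)
class ExtractionResult:
    report_id: str
    doc_type: DocType
    doc_type_confidence: float
    result_date: Optional[datetime.date]
    result_date_confidence: float
    recommendation: FollowUpRecommendation
    recommendation_confidence: float
    resolved_due_date: Optional[datetime.date]
    readiness: Readiness

    def __post_init__(self) -> None:
        resolvable = self.result_date is not None and self.recommendation.kind is not RecKind.NONE
        if (self.resolved_due_date is not None) != resolvable:
            raise ValueError("resolved_due_date present iff result date and recommendation present")
        if self.readiness is Readiness.RPA_READY and not resolvable:
            raise ValueError("RPA_READY requires result date and a non-NONE recommendation")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

# Confidence heuristic anchors: labeled-context date match is high, a bare
# letterhead date is mid (below the gate by design); a cue-adjacent
# follow-up phrase is high, a cue-less one mid; conflicting candidates
# decrement the score.
CONF_LABELED_DATE = 0.95
CONF_FALLBACK_DATE = 0.50
CONF_CUED_PHRASE = 0.90
CONF_UNCUED_PHRASE = 0.60
CONFLICT_PENALTY = 0.15

DEFAULT_DATE_LABELS = [
    "procedure date",
    "date of procedure",
    "exam date",
    "date of exam",
    "date of service",
]

# Grammar patterns are scanned in this priority order; first pattern with a
# match wins. Units accepted: years (y/yr/yrs) and months (mo/mos).
_UNIT = r"(years?|yrs?|y|months?|mos?|mo)\b"
DEFAULT_PHRASE_GRAMMAR = [
    {
        "name": "negation",
        "kind": "NONE",
        "pattern": r"no\s+(?:further|additional)\s+(?:surveillance|follow[-\s]?up|colonoscopy)",
    },
    {
        "name": "range",
        "kind": "RANGE",
        "pattern": r"(?:in|within)?\s*\b(\d{1,3})\s*(?:-|‐|‑|‒|–|—|to)\s*(\d{1,3})\s*" + _UNIT,
    },
    {
        "name": "interval",
        "kind": "INTERVAL",
        "pattern": r"\b(?:in|within|after|every)\s+(\d{1,3})\s*" + _UNIT,
    },
    {
        "name": "explicit_date",
        "kind": "EXPLICIT_DATE",
        "pattern": None,  # date token preceded by a follow-up cue; uses the date dialects
    },
]

DEFAULT_DATE_DIALECTS = ["iso", "us_slash", "long_month"]

#: Cue words marking a follow-up statement; a pattern match within
#: ``CUE_WINDOW`` characters after a cue is considered cue-adjacent.
FOLLOW_UP_CUES = (
    "recommend",
    "recommendation",
    "repeat",
    "return",
    "plan",
    "follow-up",
    "follow up",
    "followup",
    "surveillance",
    "next",
    "due",
)
CUE_WINDOW = 80

DEFAULT_COLONOSCOPY_TERMS = [
    "colonoscopy",
    "colonoscope",
    "cecum",
    "withdrawal",
    "polypectomy",
    "bowel prep",
    "terminal ileum",
    "splenic flexure",
    "sigmoid",
    "intubated",
]
DEFAULT_PATHOLOGY_TERMS = [
    "specimen",
    "microscopic",
    "histologic",
    "biopsy",
    "adenoma",
    "formalin",
    "gross description",
    "mucosa",
]


@dataclass
class ExtractionConfig:
    """Auditable configuration: ordered patterns, dialects and the gate.

    ``readiness_threshold`` defaults to 0.70 and the gate is strict
    (confidence must exceed, not meet, the threshold).
    """

    readiness_threshold: float = 0.70
    date_labels: list[str] = field(default_factory=lambda: list(DEFAULT_DATE_LABELS))
    phrase_grammar: list[dict] = field(
        default_factory=lambda: [dict(p) for p in DEFAULT_PHRASE_GRAMMAR]
    )
    date_dialects: list[str] = field(default_factory=lambda: list(DEFAULT_DATE_DIALECTS))
    colonoscopy_terms: list[str] = field(
        default_factory=lambda: list(DEFAULT_COLONOSCOPY_TERMS)
    )
    pathology_terms: list[str] = field(default_factory=lambda: list(DEFAULT_PATHOLOGY_TERMS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.readiness_threshold <= 1.0:
            raise ValueError("readiness_threshold must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "readiness_threshold": self.readiness_threshold,
                    "date_labels": self.date_labels,
                    "phrase_grammar": self.phrase_grammar,
                    "date_dialects": self.date_dialects,
                    "colonoscopy_terms": self.colonoscopy_terms,
                    "pathology_terms": self.pathology_terms,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "ExtractionConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# --------------------------------------------------------------------------
# date token scanning
# --------------------------------------------------------------------------

_MONTH_NAMES = {
    name: i + 1
    for i, name in enumerate(
        [
            "january", "february", "march", "april", "may", "june",
            "july", "august", "september", "october", "november", "december",
        ]
    )
}
for _full, _num in list(_MONTH_NAMES.items()):
    _MONTH_NAMES[_full[:3]] = _num

_MONTH_ALT = "|".join(
    sorted({m.capitalize() for m in _MONTH_NAMES} | set(_MONTH_NAMES), key=len, reverse=True)
)

# US-context dialects only: ISO, MM/DD/YYYY and long-form English months.
_DATE_PATTERNS = {
    "iso": re.compile(r"\b(\d{4})-(\d{1,2})-(\d{1,2})\b"),
    "us_slash": re.compile(r"\b(\d{1,2})/(\d{1,2})/(\d{4})\b"),
    "long_month": re.compile(
        r"\b(" + _MONTH_ALT + r")\.?\s+(\d{1,2}),?\s+(\d{4})\b", re.IGNORECASE
    ),
}


@dataclass(frozen=True)
class DateToken:
    start: int
    end: int
    value: datetime.date


def _token_from_match(dialect: str, m: re.Match) -> Optional[DateToken]:
    try:
        if dialect == "iso":
            value = datetime.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        elif dialect == "us_slash":
            value = datetime.date(int(m.group(3)), int(m.group(1)), int(m.group(2)))
        else:
            month = _MONTH_NAMES[m.group(1).lower()[:3]]
            value = datetime.date(int(m.group(3)), month, int(m.group(2)))
    except (ValueError, KeyError):
        return None
    return DateToken(start=m.start(), end=m.end(), value=value)


def find_dates(text: str, dialects: Optional[list[str]] = None) -> list[DateToken]:
    """All date tokens in ``text``, in document order, invalid dates skipped."""
    tokens: list[DateToken] = []
    for dialect in dialects or DEFAULT_DATE_DIALECTS:
        pattern = _DATE_PATTERNS[dialect]
        for m in pattern.finditer(text):
            token = _token_from_match(dialect, m)
            if token is not None:
                tokens.append(token)
    tokens.sort(key=lambda t: t.start)
    # drop tokens nested inside an earlier token's span (dialect overlap)
    out: list[DateToken] = []
    for token in tokens:
        if out and token.start < out[-1].end:
            continue
        out.append(token)
    return out


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def _count_terms(text_lower: str, terms: list[str]) -> int:
    hits = 0
    for term in terms:
        if re.search(r"\b" + re.escape(term) + r"\b", text_lower):
            hits += 1
    return hits


def classify_document(raw_text: str, config: ExtractionConfig) -> tuple[DocType, float]:
    """Classify report type from keyword lexicon hits.

    Procedure vocabulary votes COLONOSCOPY, histology vocabulary votes
    PATHOLOGY. Confidence combines purity (winner share of all hits) with
    evidence saturation (3+ distinct terms ⇒ full weight). Zero or tied
    evidence yields OTHER with confidence 0.
    """
    text_lower = raw_text.lower()
    colo = _count_terms(text_lower, config.colonoscopy_terms)
    path = _count_terms(text_lower, config.pathology_terms)
    if colo == path:  # includes the zero-evidence case
        return DocType.OTHER, 0.0
    winner, w_hits = (DocType.COLONOSCOPY, colo) if colo > path else (DocType.PATHOLOGY, path)
    confidence = (w_hits / (colo + path)) * min(1.0, w_hits / 3.0)
    return winner, round(confidence, 4)


def extract_result_date(
    raw_text: str, config: ExtractionConfig
) -> tuple[Optional[datetime.date], float]:
    """Extract the procedure/result date.

    Dates following a labeled context ("Procedure date:", "Date of
    procedure", "Exam date", ...) outrank any unlabeled (letterhead)
    date. Multiple labeled contexts naming different dates decrement the
    confidence; a bare fallback date scores below the readiness gate.
    """
    tokens = find_dates(raw_text, config.date_dialects)
    if not tokens:
        return None, 0.0
    label_re = re.compile(
        "(?:" + "|".join(re.escape(lbl) for lbl in config.date_labels) + r")\s*[:\-]?\s*",
        re.IGNORECASE,
    )
    labeled: list[DateToken] = []
    for m in label_re.finditer(raw_text):
        for token in tokens:
            if m.end() <= token.start <= m.end() + 40:
                labeled.append(token)
                break
    if labeled:
        chosen = labeled[0]
        conflicts = len({t.value for t in labeled}) - 1
        confidence = CONF_LABELED_DATE - CONFLICT_PENALTY * min(conflicts, 2)
        return chosen.value, round(max(confidence, 0.0), 4)
    # letterhead fallback: first date in the document, deliberately mid-range
    return tokens[0].value, CONF_FALLBACK_DATE


_CUE_RE = re.compile("|".join(re.escape(c) for c in FOLLOW_UP_CUES), re.IGNORECASE)


def _unit_months(unit: str) -> int:
    return 1 if unit.lower().startswith("m") else 12


@dataclass(frozen=True)
class _Candidate:
    rec: FollowUpRecommendation
    cue_distance: float
    order_key: tuple


def _cue_distance(cue_starts: list[int], match_start: int) -> float:
    best = float("inf")
    for start in cue_starts:
        if start <= match_start and match_start - start <= CUE_WINDOW:
            best = min(best, match_start - start)
    return best


def extract_follow_up(
    raw_text: str, config: ExtractionConfig
) -> tuple[FollowUpRecommendation, float]:
    """Parse the follow-up recommendation from free text.

    The phrase grammar is scanned in priority order (negation, range,
    interval, explicit date); the first pattern with any match wins.
    Among several statements matching the same pattern, the one nearest a
    recommendation cue wins, ties broken toward the earlier resolved date
    — the conservative choice. No cue anywhere ⇒ kind NONE, confidence 0.
    """
    cue_starts = [m.start() for m in _CUE_RE.finditer(raw_text)]
    date_tokens: Optional[list[DateToken]] = None

    for spec_entry in config.phrase_grammar:
        candidates: list[_Candidate] = []
        name = spec_entry["name"]
        if spec_entry.get("pattern"):
            pattern = re.compile(spec_entry["pattern"], re.IGNORECASE)
            for m in pattern.finditer(raw_text):
                rec = _candidate_from_match(name, m)
                if rec is None:
                    continue
                candidates.append(
                    _Candidate(
                        rec=rec,
                        cue_distance=_cue_distance(cue_starts, m.start()),
                        order_key=_resolution_key(rec, m.start()),
                    )
                )
        elif name == "explicit_date":
            if date_tokens is None:
                date_tokens = find_dates(raw_text, config.date_dialects)
            for token in date_tokens:
                dist = _cue_distance(cue_starts, token.start)
                if dist == float("inf"):
                    continue  # an un-cued date is a header date, not a recommendation
                rec = FollowUpRecommendation(
                    kind=RecKind.EXPLICIT_DATE,
                    explicit_date=token.value,
                    source_span=(token.start, token.end),
                )
                candidates.append(
                    _Candidate(rec=rec, cue_distance=dist, order_key=_resolution_key(rec, token.start))
                )
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c.cue_distance, c.order_key))
        best = candidates[0]
        if best.rec.kind is RecKind.NONE:
            return best.rec, CONF_CUED_PHRASE
        confidence = (
            CONF_CUED_PHRASE if best.cue_distance != float("inf") else CONF_UNCUED_PHRASE
        )
        distinct = {
            (c.rec.kind, c.rec.low_months, c.rec.high_months, c.rec.explicit_date)
            for c in candidates
        }
        if len(distinct) > 1:
            confidence -= CONFLICT_PENALTY
        return best.rec, round(max(confidence, 0.0), 4)

    return NO_RECOMMENDATION, 0.0


def _candidate_from_match(name: str, m: re.Match) -> Optional[FollowUpRecommendation]:
    span = (m.start(), m.end())
    if name == "negation":
        return FollowUpRecommendation(kind=RecKind.NONE)
    if name == "range":
        low, high = int(m.group(1)), int(m.group(2))
        months = _unit_months(m.group(3))
        low, high = low * months, high * months
        if low <= 0 or high <= 0 or low > high:
            return None
        if low == high:
            return FollowUpRecommendation(
                kind=RecKind.INTERVAL, low_months=low, high_months=low, source_span=span
            )
        return FollowUpRecommendation(
            kind=RecKind.RANGE, low_months=low, high_months=high, source_span=span
        )
    if name == "interval":
        n = int(m.group(1)) * _unit_months(m.group(2))
        if n <= 0:
            return None
        return FollowUpRecommendation(
            kind=RecKind.INTERVAL, low_months=n, high_months=n, source_span=span
        )
    raise ValueError(f"unknown grammar pattern {name!r}")


def _resolution_key(rec: FollowUpRecommendation, start: int) -> tuple:
    # earlier resolved date first: smaller interval / earlier explicit date
    if rec.kind is RecKind.EXPLICIT_DATE:
        return (1, rec.explicit_date.toordinal(), start)
    if rec.kind in (RecKind.INTERVAL, RecKind.RANGE):
        return (0, rec.low_months, start)
    return (2, 0, start)


def resolve_due_date(
    recommendation: FollowUpRecommendation, result_date: datetime.date
) -> Optional[datetime.date]:
    """Resolve a recommendation into the proposed due date.

    Ranges resolve to their earlier bound — the clinically conservative
    choice. Month addition clamps to the last valid day of the target
    month (e.g. Feb 29 + 120 months → Feb 28).
    """
    kind = recommendation.kind
    if kind is RecKind.NONE:
        return None
    if kind is RecKind.EXPLICIT_DATE:
        return recommendation.explicit_date
    months = recommendation.low_months
    if months is None or months <= 0:
        raise ValueError("malformed recommendation: non-positive interval")
    return result_date + relativedelta(months=months)


def assess_readiness(extraction: "ExtractionResult", config: ExtractionConfig) -> Readiness:
    """Gate a report for automated processing.

    Ready only when a result date and a non-NONE recommendation are both
    present and the *minimum* of their confidences strictly exceeds the
    threshold; anything else routes to human review.
    """
    if extraction.result_date is None or extraction.recommendation.kind is RecKind.NONE:
        return Readiness.NOT_READY
    if (
        min(extraction.result_date_confidence, extraction.recommendation_confidence)
        > config.readiness_threshold
    ):
        return Readiness.RPA_READY
    return Readiness.NOT_READY


def extract(report, config: Optional[ExtractionConfig] = None) -> ExtractionResult:
    """Run the full extraction pass over one scanned report."""
    config = config or ExtractionConfig()
    doc_type, doc_conf = classify_document(report.raw_text, config)
    result_date, date_conf = extract_result_date(report.raw_text, config)
    recommendation, rec_conf = extract_follow_up(report.raw_text, config)
    resolved = (
        resolve_due_date(recommendation, result_date)
        if result_date is not None and recommendation.kind is not RecKind.NONE
        else None
    )
    partial = ExtractionResult(
        report_id=report.report_id,
        doc_type=doc_type,
        doc_type_confidence=doc_conf,
        result_date=result_date,
        result_date_confidence=date_conf,
        recommendation=recommendation,
        recommendation_confidence=rec_conf,
        resolved_due_date=resolved,
        readiness=Readiness.NOT_READY,
    )
    return replace(partial, readiness=assess_readiness(partial, config))
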