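"""Seeded synthetic corpus: report texts, snapshots and ground truth.

Generates colonoscopy / pathology / other report texts with known
extraction targets, plus a patient-snapshot table engineered so that
each report triggers a chosen decision path (clean update, one of the
blocking rules, or the staleness guard). Every emitted scenario is
self-checked against the decision engine's brute-force predicate oracle,
so a generated label is guaranteed to be the rule the engine will hit.

Defaults encode the operating conditions the pipeline is meant for: a
document mix of 90.6% colonoscopy / 6.7% pathology / 2.7% other, about
57% of colonoscopy reports carrying a follow-up recommendation, and
guideline-plausible surveillance intervals (1–10 years). ``noise_level``
injects character-level corruption into the recommendation phrasing —
the kind of OCR damage the grammar is documented to break on — which
routes the affected reports to human review.
"""

from __future__ import annotations

import dataclasses
import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import decisions as dec
from . import extraction as ex
from .intake import ScannedReport, write_manifest

EPOCH = datetime.date(2022, 1, 1)
WINDOW_DAYS = 1096  # procedures drawn from 2022–2024

SCENARIOS = ("clean", "E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8", "E9", "STALE")

GROUND_TRUTH_COLUMNS = [
    "report_id",
    "patient_id",
    "true_doc_type",
    "true_result_date",
    "true_rec_kind",
    "true_low_months",
    "true_high_months",
    "true_explicit_date",
    "true_due_date",
    "true_label",
    "corrupted",
]


class CorpusConfigError(ValueError):
    """The requested scenario mix cannot be realized."""


def _default_exception_mix() -> dict[str, float]:
    return {
        "clean": 0.65,
        "E1": 0.05,
        "E2": 0.05,
        "E3": 0.05,
        "E4": 0.04,
        "E5": 0.0,  # unreachable downstream of the readiness gate
        "E6": 0.03,
        "E7": 0.04,
        "E8": 0.03,
        "E9": 0.03,
        "STALE": 0.03,
    }


@dataclass
class ScenarioConfig:
    """Knobs of the generator; defaults are the intended study conditions."""

    n_reports: int = 100
    seed: int = 0
    doc_type_mix: tuple[float, float, float] = (0.906, 0.067, 0.027)
    p_follow_up_present: float = 0.57
    p_range: float = 0.20
    p_explicit_date: float = 0.10
    interval_pool_months: tuple[int, ...] = (12, 36, 60, 84, 120)
    long_interval_months: int = 156  # drives the over-10-year exception
    exception_mix: dict[str, float] = field(default_factory=_default_exception_mix)
    date_dialect_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)  # iso / us_slash / long_month
    noise_level: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise CorpusConfigError("n_reports must be >= 1")
        for name, weights in (
            ("doc_type_mix", self.doc_type_mix),
            ("date_dialect_mix", self.date_dialect_mix),
        ):
            if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
                raise CorpusConfigError(f"{name} must be non-negative and sum to 1")
        unknown = set(self.exception_mix) - set(SCENARIOS)
        if unknown:
            raise CorpusConfigError(f"unknown scenario keys: {sorted(unknown)}")
        if abs(sum(self.exception_mix.values()) - 1.0) > 1e-9:
            raise CorpusConfigError("exception_mix must sum to 1")
        if any(w < 0 for w in self.exception_mix.values()):
            raise CorpusConfigError("exception_mix weights must be non-negative")
        if self.exception_mix.get("E5", 0.0) > 0:
            raise CorpusConfigError(
                "E5 cannot be generated: the readiness gate guarantees an "
                "assessable follow-up date before the decision engine runs"
            )
        if not 0.0 <= self.noise_level <= 1.0:
            raise CorpusConfigError("noise_level must lie in [0, 1]")
        if not 0.0 <= self.p_follow_up_present <= 1.0:
            raise CorpusConfigError("p_follow_up_present must lie in [0, 1]")
        if self.p_range + self.p_explicit_date > 1.0:
            raise CorpusConfigError("p_range + p_explicit_date must not exceed 1")


@dataclass(frozen=True)
class TrueFields:
    """Per-report ground truth, consistent with the emitted text by construction."""

    report_id: str
    patient_id: str
    doc_type: ex.DocType
    result_date: Optional[datetime.date]
    rec_kind: ex.RecKind
    low_months: Optional[int]
    high_months: Optional[int]
    explicit_date: Optional[datetime.date]
    due_date: Optional[datetime.date]
    label: str  # "no_date", "clean", or a blocking-rule code
    corrupted: bool


@dataclass
class CorpusBundle:
    reports: list[ScannedReport]
    snapshots: dict[str, dec.PatientSnapshot]
    truth: list[TrueFields]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                {
                    "report_id": t.report_id,
                    "patient_id": t.patient_id,
                    "true_doc_type": t.doc_type.value,
                    "true_result_date": t.result_date.isoformat() if t.result_date else "",
                    "true_rec_kind": t.rec_kind.value,
                    "true_low_months": t.low_months if t.low_months is not None else "",
                    "true_high_months": t.high_months if t.high_months is not None else "",
                    "true_explicit_date": t.explicit_date.isoformat() if t.explicit_date else "",
                    "true_due_date": t.due_date.isoformat() if t.due_date else "",
                    "true_label": t.label,
                    "corrupted": int(t.corrupted),
                }
            )
        return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


# --------------------------------------------------------------------------
# text templates
# --------------------------------------------------------------------------

_CLINICS = (
    "Riverside", "Lakeview", "Summit", "Harbor Point", "Maplewood",
    "Northgate", "Crestline", "Bayside",
)

_DATE_LABELS = ("Procedure Date", "Date of Procedure", "Exam Date")

_FINDINGS = (
    "A 6 mm sessile polyp in the sigmoid colon was removed by snare polypectomy.",
    "Two diminutive polyps were removed by cold forceps polypectomy.",
    "No polyps were identified. The mucosa appeared normal throughout.",
    "A small polyp in the ascending colon was removed by polypectomy and retrieved.",
)

_REC_INTERVAL = (
    "Recommendation: repeat colonoscopy in {n} {unit}.",
    "We recommend a repeat colonoscopy in {n} {unit}.",
    "The patient should return in {n} {unit} for surveillance colonoscopy.",
    "Plan: follow-up colonoscopy in {n} {unit}.",
)
_REC_RANGE = (
    "Recommendation: repeat colonoscopy in {a}-{b} {unit}.",
    "The patient should return in {a} to {b} {unit} for surveillance.",
    "Recommend repeat colonoscopy in {a}‐{b} {unit}.",
)
_REC_EXPLICIT = (
    "The next colonoscopy is due on {date}.",
    "Recommendation: repeat colonoscopy on {date}.",
)
_REC_DEFERRED = (
    "Recommendation: pending pathology results.",
    "Follow-up interval to be determined after pathology review.",
)
_REC_NEGATION = (
    "No further surveillance colonoscopy is indicated.",
    "No additional follow-up is recommended for this patient.",
)


def _render_date(day: datetime.date, dialect: str) -> str:
    if dialect == "iso":
        return day.isoformat()
    if dialect == "us_slash":
        return f"{day.month:02d}/{day.day:02d}/{day.year}"
    return f"{day.strftime('%B')} {day.day}, {day.year}"


def _render_months(months: int, rng: np.random.Generator) -> tuple[int, str]:
    if months % 12 == 0 and rng.random() < 0.7:
        unit = str(rng.choice(["years", "y", "yr"]))
        return months // 12, unit
    return months, str(rng.choice(["months", "mo"]))


def _corrupt_phrase(sentence: str) -> str:
    """OCR-style damage: destroy the whitespace and digits the grammar needs."""
    return re.sub(r"\d", "#", sentence.replace(" ", "~"))


def generate_report_text(
    true_fields: TrueFields,
    dialect: str,
    corrupted: bool,
    rng: np.random.Generator,
    scan_date: datetime.date,
) -> str:
    """Render one report's prose around the ground-truth fields."""
    clinic = str(rng.choice(_CLINICS))
    if true_fields.doc_type is ex.DocType.COLONOSCOPY:
        return _colonoscopy_text(true_fields, dialect, corrupted, rng, clinic, scan_date)
    if true_fields.doc_type is ex.DocType.PATHOLOGY:
        return _pathology_text(true_fields, dialect, rng, clinic)
    return _other_text(rng, clinic, scan_date, dialect)


def _recommendation_sentence(t: TrueFields, dialect: str, rng: np.random.Generator) -> str:
    if t.rec_kind is ex.RecKind.INTERVAL:
        n, unit = _render_months(t.low_months, rng)
        return str(rng.choice(_REC_INTERVAL)).format(n=n, unit=unit)
    if t.rec_kind is ex.RecKind.RANGE:
        # ranges always render in years with a shared unit (e.g. "3-5 y")
        a, b = t.low_months // 12, t.high_months // 12
        unit = str(rng.choice(["years", "y", "yr"]))
        return str(rng.choice(_REC_RANGE)).format(a=a, b=b, unit=unit)
    if t.rec_kind is ex.RecKind.EXPLICIT_DATE:
        return str(rng.choice(_REC_EXPLICIT)).format(date=_render_date(t.explicit_date, dialect))
    if t.label == "no_date" and rng.random() < 0.3:
        return str(rng.choice(_REC_NEGATION))
    return str(rng.choice(_REC_DEFERRED))


def _colonoscopy_text(
    t: TrueFields,
    dialect: str,
    corrupted: bool,
    rng: np.random.Generator,
    clinic: str,
    scan_date: datetime.date,
) -> str:
    label = str(rng.choice(_DATE_LABELS))
    finding = str(rng.choice(_FINDINGS))
    rec = _recommendation_sentence(t, dialect, rng)
    if corrupted:
        rec = _corrupt_phrase(rec)
    withdrawal = int(rng.integers(6, 15))
    lines = [
        f"{clinic.upper()} ENDOSCOPY CENTER",
        "",
        "COLONOSCOPY REPORT",
        "",
        f"Patient: {t.patient_id}",
        f"{label}: {_render_date(t.result_date, dialect)}",
        "Indication: colorectal cancer screening.",
        "",
        "Procedure: The colonoscope was advanced under direct visualization",
        "to the cecum. The quality of the bowel prep was adequate.",
        f"Withdrawal time was {withdrawal} minutes.",
        f"Findings: {finding}",
        "",
        rec,
        "",
        "Electronically signed by the endoscopist.",
    ]
    return "\n".join(lines)


def _pathology_text(
    t: TrueFields, dialect: str, rng: np.random.Generator, clinic: str
) -> str:
    collected = _render_date(t.result_date, dialect) if t.result_date else ""
    dx = str(
        rng.choice(
            [
                "Tubular adenoma, completely excised.",
                "Hyperplastic change of the mucosa, no dysplasia identified.",
                "Fragments of benign mucosa with no histologic abnormality.",
            ]
        )
    )
    lines = [
        f"{clinic.upper()} PATHOLOGY LABORATORY",
        "",
        "SURGICAL PATHOLOGY REPORT",
        "",
        f"Patient: {t.patient_id}",
        f"Specimen collected: {collected}",
        "Specimen: polyp, cold forceps biopsy, submitted in formalin.",
        "Gross description: tan-pink tissue fragments measuring 0.4 cm in aggregate.",
        f"Microscopic description: {dx}",
        "",
        "Histologic sections reviewed. Report electronically verified.",
    ]
    return "\n".join(lines)


def _other_text(
    rng: np.random.Generator, clinic: str, scan_date: datetime.date, dialect: str
) -> str:
    lines = [
        f"{clinic} Medical Associates",
        f"{_render_date(scan_date, dialect)}",
        "",
        "Dear Doctor,",
        "",
        "Enclosed please find the requested records for your patient.",
        "Please contact our office with any questions regarding this",
        "correspondence or to request additional documentation.",
        "",
        "Sincerely,",
        "Medical Records Department",
    ]
    return "\n".join(lines)


# --------------------------------------------------------------------------
# scenario assembly
# --------------------------------------------------------------------------


def _add_months(day: datetime.date, months: int) -> datetime.date:
    return dec._add_months_clamped(day, months)


def _draw_recommendation(
    cfg: ScenarioConfig, rng: np.random.Generator, scenario: str
) -> tuple[ex.RecKind, int, int, Optional[int]]:
    """Return (kind, low, high, explicit_offset_months) in months."""
    if scenario == "E4":
        low = cfg.long_interval_months
        u = rng.random()
        if u < cfg.p_range:
            return ex.RecKind.RANGE, low, low + 24, None
        if u < cfg.p_range + cfg.p_explicit_date:
            return ex.RecKind.EXPLICIT_DATE, low, low, low
        return ex.RecKind.INTERVAL, low, low, None
    pool = list(cfg.interval_pool_months)
    u = rng.random()
    if u < cfg.p_range:
        short = sorted(p for p in pool if p % 12 == 0 and p < max(pool))
        low = int(rng.choice(short))
        larger = [p for p in pool if p > low and p % 12 == 0]
        high = int(rng.choice(larger))
        return ex.RecKind.RANGE, low, high, None
    low = int(rng.choice(pool))
    if u < cfg.p_range + cfg.p_explicit_date:
        return ex.RecKind.EXPLICIT_DATE, low, low, low
    return ex.RecKind.INTERVAL, low, low, None


def _build_snapshot(
    scenario: str,
    patient_id: str,
    result_date: datetime.date,
    due_date: datetime.date,
    linked_date: datetime.date,
    rng: np.random.Generator,
) -> Optional[dec.PatientSnapshot]:
    """Snapshot engineered so exactly the scenario's rule blocks (or none)."""
    if scenario == "E8":
        return None
    age = int(rng.integers(45, 76))
    orders = (
        dec.Order(
            order_id=f"O-{patient_id}",
            order_date=linked_date - datetime.timedelta(days=int(rng.integers(5, 90))),
            outstanding=True,
        ),
    )
    later_due = _add_months(due_date, int(rng.integers(6, 36)))
    base = dict(
        patient_id=patient_id,
        age_years=age,
        hm_topic_assigned=True,
        current_due_date=later_due,
        frequency_modifier=False,
        manual_assignment_date=None,
        last_documented_colonoscopy_date=result_date
        - datetime.timedelta(days=int(rng.integers(400, 2400))),
        orders=orders,
    )
    if scenario == "E1":
        offset = int(rng.integers(0, 12))
        base["current_due_date"] = _add_months(due_date, -offset)
    elif scenario == "E2":
        base["frequency_modifier"] = True
    elif scenario == "E3":
        base["manual_assignment_date"] = linked_date + datetime.timedelta(
            days=int(rng.integers(1, 60))
        )
    elif scenario == "E4":
        base["current_due_date"] = None
    elif scenario == "E7":
        base["hm_topic_assigned"] = False
        base["age_years"] = int(rng.choice([int(rng.integers(30, 45)), int(rng.integers(76, 95))]))
    elif scenario == "E9":
        variant = rng.integers(0, 3)
        if variant == 0:
            base["orders"] = ()
        elif variant == 1:
            base["orders"] = (dataclasses.replace(orders[0], outstanding=False),)
        else:
            base["orders"] = (
                dataclasses.replace(
                    orders[0],
                    order_date=linked_date + datetime.timedelta(days=int(rng.integers(1, 30))),
                ),
            )
    elif scenario == "STALE":
        newer = result_date + datetime.timedelta(days=int(rng.integers(30, 300)))
        base["last_documented_colonoscopy_date"] = newer
        base["current_due_date"] = _add_months(newer, 120)
    return dec.PatientSnapshot(**base)


def _neutral_snapshot(patient_id: str, anchor: datetime.date, rng: np.random.Generator) -> dec.PatientSnapshot:
    """Snapshot for a report that never reaches the decision engine."""
    return dec.PatientSnapshot(
        patient_id=patient_id,
        age_years=int(rng.integers(45, 76)),
        hm_topic_assigned=True,
        current_due_date=_add_months(anchor, 120),
        orders=(
            dec.Order(
                order_id=f"O-{patient_id}",
                order_date=anchor - datetime.timedelta(days=int(rng.integers(5, 90))),
                outstanding=True,
            ),
        ),
    )


def _verify_scenario(
    truth: TrueFields,
    report: ScannedReport,
    snapshot: Optional[dec.PatientSnapshot],
) -> None:
    """Self-check: the emitted pair must trigger exactly the intended rule."""
    synthetic_extraction = ex.ExtractionResult(
        report_id=truth.report_id,
        doc_type=truth.doc_type,
        doc_type_confidence=1.0,
        result_date=truth.result_date,
        result_date_confidence=1.0,
        recommendation=_truth_recommendation(truth),
        recommendation_confidence=1.0,
        resolved_due_date=truth.due_date,
        readiness=ex.Readiness.RPA_READY,
    )
    flags = dec.audit_predicates(synthetic_extraction, report, snapshot)
    code = dec.first_blocking_code(flags)
    expected = None if truth.label == "clean" else truth.label
    if code != expected:
        raise CorpusConfigError(
            f"{truth.report_id}: scenario {truth.label!r} emitted predicate {code!r}"
        )


def _truth_recommendation(t: TrueFields) -> ex.FollowUpRecommendation:
    if t.rec_kind is ex.RecKind.EXPLICIT_DATE:
        return ex.FollowUpRecommendation(kind=t.rec_kind, explicit_date=t.explicit_date)
    return ex.FollowUpRecommendation(kind=t.rec_kind, low_months=t.low_months, high_months=t.high_months)


DIALECTS = ("iso", "us_slash", "long_month")
DOC_TYPES = (ex.DocType.COLONOSCOPY, ex.DocType.PATHOLOGY, ex.DocType.OTHER)


def generate_corpus(
    config: ScenarioConfig, out_dir: Optional[str | Path] = None
) -> CorpusBundle:
    """Generate the corpus; optionally write it to ``out_dir``.

    Fully reproducible: a single root seed is fanned out per report index
    (``default_rng([seed, i])``), so any subset of reports regenerates
    identically. When ``out_dir`` is given, writes ``manifest.csv``,
    ``reports/*.txt``, ``snapshots.csv`` and ``ground_truth.csv``.
    """
    reports: list[ScannedReport] = []
    snapshots: dict[str, dec.PatientSnapshot] = {}
    truths: list[TrueFields] = []

    scen_names = list(config.exception_mix)
    scen_weights = np.array([config.exception_mix[k] for k in scen_names], dtype=float)
    scen_weights = scen_weights / scen_weights.sum()

    for i in range(config.n_reports):
        rng = np.random.default_rng([config.seed, i])
        report_id = f"R{i + 1:05d}"
        patient_id = f"P{i + 1:05d}"
        doc_type = DOC_TYPES[int(rng.choice(3, p=np.asarray(config.doc_type_mix)))]
        dialect = DIALECTS[int(rng.choice(3, p=np.asarray(config.date_dialect_mix)))]
        result_date = EPOCH + datetime.timedelta(days=int(rng.integers(0, WINDOW_DAYS)))
        scan_date = result_date + datetime.timedelta(days=int(rng.integers(3, 30)))
        noise_draw = rng.random()  # always drawn: couples corpora across noise levels
        corrupted = False

        follow_up = (
            doc_type is ex.DocType.COLONOSCOPY and rng.random() < config.p_follow_up_present
        )
        if not follow_up:
            truth = TrueFields(
                report_id=report_id,
                patient_id=patient_id,
                doc_type=doc_type,
                result_date=result_date if doc_type is not ex.DocType.OTHER else None,
                rec_kind=ex.RecKind.NONE,
                low_months=None,
                high_months=None,
                explicit_date=None,
                due_date=None,
                label="no_date",
                corrupted=False,
            )
            linked = result_date if doc_type is not ex.DocType.OTHER else None
            snapshot = _neutral_snapshot(patient_id, result_date, rng)
        else:
            scenario = scen_names[int(rng.choice(len(scen_names), p=scen_weights))]
            kind, low, high, explicit_offset = _draw_recommendation(config, rng, scenario)
            explicit_date = (
                _add_months(result_date, explicit_offset) if explicit_offset is not None else None
            )
            due = explicit_date if kind is ex.RecKind.EXPLICIT_DATE else _add_months(result_date, low)
            corrupted = noise_draw < config.noise_level
            linked = result_date
            if scenario == "E6":
                linked = result_date - datetime.timedelta(days=int(rng.integers(1, 10)))
            truth = TrueFields(
                report_id=report_id,
                patient_id=patient_id,
                doc_type=doc_type,
                result_date=result_date,
                rec_kind=kind,
                low_months=low if kind is not ex.RecKind.EXPLICIT_DATE else None,
                high_months=high if kind is not ex.RecKind.EXPLICIT_DATE else None,
                explicit_date=explicit_date,
                due_date=due,
                label=scenario,
                corrupted=corrupted,
            )
            snapshot = _build_snapshot(scenario, patient_id, result_date, due, linked, rng)

        text = generate_report_text(truth, dialect, corrupted, rng, scan_date)
        report = ScannedReport(
            report_id=report_id,
            patient_id=patient_id,
            raw_text=text,
            scan_date=scan_date,
            linked_procedure_date=linked,
            source_label="synthetic",
        )
        if truth.label not in ("no_date",):
            _verify_scenario(truth, report, snapshot)
        reports.append(report)
        if snapshot is not None:
            snapshots[patient_id] = snapshot
        truths.append(truth)

    bundle = CorpusBundle(reports=reports, snapshots=snapshots, truth=truths)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: CorpusBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    reports_dir = out_dir / "reports"
    reports_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for report in bundle.reports:
        filename = f"{report.report_id}.txt"
        (reports_dir / filename).write_text(report.raw_text, encoding="utf-8")
        manifest_rows.append(
            {
                "report_id": report.report_id,
                "patient_id": report.patient_id,
                "file": filename,
                "scan_date": report.scan_date.isoformat(),
                "linked_procedure_date": (
                    report.linked_procedure_date.isoformat()
                    if report.linked_procedure_date
                    else ""
                ),
                "source_label": report.source_label,
            }
        )
    write_manifest(manifest_rows, out_dir / "manifest.csv")
    dec.write_snapshots(list(bundle.snapshots.values()), out_dir / "snapshots.csv")
    bundle.truth_frame().to_csv(out_dir / "ground_truth.csv", index=False)
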