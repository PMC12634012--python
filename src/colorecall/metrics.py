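"""Validation outcome taxonomy and aggregate process metrics.

Every processed report falls into exactly one of six outcome categories,
split by whether the report cleared the readiness gate:

* NOT_READY_CORRECT_NO_DATE — routed to review, and the report genuinely
  contains no follow-up date (correct deferral);
* NOT_READY_MISSED_DATE — routed to review although a follow-up date was
  present (a false negative of the extractor);
* NOT_READY_INACCURATE_DATE — routed to review with a wrong candidate
  date recorded;
* READY_CORRECT_UPDATE — the due date was updated and matches truth;
* READY_CORRECT_EXCEPTION — the engine correctly withheld the update
  under the blocking rule the scenario called for;
* READY_INCORRECT_UPDATE — the bot acted and was wrong (wrong date, or
  wrong blocking rule).

Aggregate metrics: *accuracy* is the fraction of reports where the
process did the right thing (correct update, correct exception, or
correct no-date deferral); the *false-negative rate* is, among reports
that actually carry a follow-up date, the fraction the extractor missed.
Both come with Wald 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .decisions import Action
from .extraction import Readiness
from .worksheet import WorksheetRow


class OutcomeCategory(str, Enum):
    NOT_READY_CORRECT_NO_DATE = "NOT_READY_CORRECT_NO_DATE"
    NOT_READY_MISSED_DATE = "NOT_READY_MISSED_DATE"
    NOT_READY_INACCURATE_DATE = "NOT_READY_INACCURATE_DATE"
    READY_CORRECT_UPDATE = "READY_CORRECT_UPDATE"
    READY_CORRECT_EXCEPTION = "READY_CORRECT_EXCEPTION"
    READY_INCORRECT_UPDATE = "READY_INCORRECT_UPDATE"


READY_CATEGORIES = (
    OutcomeCategory.READY_CORRECT_UPDATE,
    OutcomeCategory.READY_CORRECT_EXCEPTION,
    OutcomeCategory.READY_INCORRECT_UPDATE,
)
CORRECT_CATEGORIES = (
    OutcomeCategory.READY_CORRECT_UPDATE,
    OutcomeCategory.READY_CORRECT_EXCEPTION,
    OutcomeCategory.NOT_READY_CORRECT_NO_DATE,
)


@dataclass(frozen=True)
class ValidationOutcome:
    report_id: str
    category: OutcomeCategory


@dataclass(frozen=True)
class Proportion:
    """A count ratio with its Wald 95% CI, on the fraction scale."""

    count: int
    nobs: int
    value: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        """Rendered to one decimal place, as reports print proportions."""
        return round(100.0 * self.value, 1)


def proportion(count: int, nobs: int) -> Proportion:
    """Point estimate and Wald (normal-approximation) 95% CI for k/n."""
    if nobs <= 0 or count < 0 or count > nobs:
        raise ValueError(f"invalid proportion {count}/{nobs}")
    low, high = proportion_confint(count, nobs, alpha=0.05, method="normal")
    return Proportion(count=count, nobs=nobs, value=count / nobs, ci_low=low, ci_high=high)


@dataclass(frozen=True)
class MetricsReport:
    n_total: int
    counts: dict
    accuracy: Proportion
    false_negative_rate: Optional[Proportion]
    not_ready_fraction: Proportion
    correct_update_among_ready: Optional[Proportion]
    net_update_fraction: Proportion
    notes: str = ""

    def to_dict(self) -> dict:
        def prop(p: Optional[Proportion]) -> Optional[dict]:
            if p is None:
                return None
            return {
                "count": p.count,
                "n": p.nobs,
                "fraction": p.value,
                "percent": p.percent,
                "ci95_low": p.ci_low,
                "ci95_high": p.ci_high,
            }

        return {
            "n_total": self.n_total,
            "counts": {k.value if isinstance(k, OutcomeCategory) else k: v for k, v in self.counts.items()},
            "accuracy": prop(self.accuracy),
            "false_negative_rate": prop(self.false_negative_rate),
            "not_ready_fraction": prop(self.not_ready_fraction),
            "correct_update_among_ready": prop(self.correct_update_among_ready),
            "net_update_fraction": prop(self.net_update_fraction),
            "notes": self.notes,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")

    def write_csv(self, path: str | Path) -> None:
        rows = [{"category": k.value if isinstance(k, OutcomeCategory) else k, "count": v}
                for k, v in self.counts.items()]
        pd.DataFrame(rows).to_csv(path, index=False)


class GroundTruthMissing(ValueError):
    """A report had no ground-truth record to validate against."""


def classify_outcome(row: WorksheetRow, truth: Mapping) -> ValidationOutcome:
    """Map one audited report to its outcome category.

    ``truth`` must carry ``true_due_date`` (ISO string or '' when the
    report has no follow-up date) and ``true_label`` ('clean' for an
    expected update, otherwise the expected blocking-rule code).
    """
    if truth is None:
        raise GroundTruthMissing(row.report_id)
    true_due = str(truth.get("true_due_date", "") or "")
    true_label = str(truth.get("true_label", "") or "")
    truth_has_date = bool(true_due)

    if row.readiness is Readiness.NOT_READY:
        if not truth_has_date:
            category = OutcomeCategory.NOT_READY_CORRECT_NO_DATE
        elif (
            row.resolved_due_date is not None
            and row.resolved_due_date.isoformat() != true_due
        ):
            category = OutcomeCategory.NOT_READY_INACCURATE_DATE
        else:
            category = OutcomeCategory.NOT_READY_MISSED_DATE
        return ValidationOutcome(report_id=row.report_id, category=category)

    if row.action is Action.UPDATE:
        correct = (
            true_label == "clean"
            and row.new_due_date is not None
            and row.new_due_date.isoformat() == true_due
        )
        category = (
            OutcomeCategory.READY_CORRECT_UPDATE
            if correct
            else OutcomeCategory.READY_INCORRECT_UPDATE
        )
    else:
        category = (
            OutcomeCategory.READY_CORRECT_EXCEPTION
            if row.exception_code == true_label
            else OutcomeCategory.READY_INCORRECT_UPDATE
        )
    return ValidationOutcome(report_id=row.report_id, category=category)


def _metrics_from_counts(counts: Mapping[OutcomeCategory, int], notes: str = "") -> MetricsReport:
    counts = {cat: int(counts.get(cat, 0)) for cat in OutcomeCategory}
    if any(v < 0 for v in counts.values()):
        raise ValueError("outcome counts must be non-negative")
    n_total = sum(counts.values())
    if n_total < 1:
        raise ValueError("at least one outcome required")
    n_ready = sum(counts[c] for c in READY_CATEGORIES)
    n_correct = sum(counts[c] for c in CORRECT_CATEGORIES)
    missed = counts[OutcomeCategory.NOT_READY_MISSED_DATE]
    # date-bearing denominator: missed reports plus everything the gate
    # passed (a gated report carries an extracted date by construction)
    fn_denominator = missed + n_ready
    fn = proportion(missed, fn_denominator) if fn_denominator > 0 else None
    not_ready = n_total - n_ready
    return MetricsReport(
        n_total=n_total,
        counts=counts,
        accuracy=proportion(n_correct, n_total),
        false_negative_rate=fn,
        not_ready_fraction=proportion(not_ready, n_total),
        correct_update_among_ready=(
            proportion(counts[OutcomeCategory.READY_CORRECT_UPDATE], n_ready)
            if n_ready > 0
            else None
        ),
        net_update_fraction=proportion(counts[OutcomeCategory.READY_CORRECT_UPDATE], n_total),
        notes=notes
        or (
            "false_negative_rate undefined (no date-bearing reports)"
            if fn is None
            else ""
        ),
    )


def compute_metrics(outcomes: Sequence[ValidationOutcome]) -> MetricsReport:
    """Aggregate per-report outcomes into the process metrics."""
    counts: dict[OutcomeCategory, int] = {cat: 0 for cat in OutcomeCategory}
    for outcome in outcomes:
        counts[outcome.category] += 1
    return _metrics_from_counts(counts)


def tally_from_counts(counts: Mapping) -> MetricsReport:
    """Worked-example mode: apply the metric formulas to supplied counts.

    Keys may be :class:`OutcomeCategory` members or their string names.
    No pipeline run happens; this audits printed tallies.
    """
    normalized: dict[OutcomeCategory, int] = {}
    for key, value in counts.items():
        cat = key if isinstance(key, OutcomeCategory) else OutcomeCategory(str(key))
        value = int(value)
        if value < 0:
            raise ValueError(f"negative count for {cat.value}")
        normalized[cat] = value
    return _metrics_from_counts(normalized, notes="worked-example tally")
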