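# Methods

## Scope and model

`colorecall` models a documentation workflow, not a clinical judgement: given
an unstructured colonoscopy report, decide whether the EHR health-maintenance
(HM) colonoscopy due date may safely be replaced by the report's recommended
follow-up, and otherwise say precisely why not. The pipeline has three
stages — intake, extraction with a confidence gate, and a rule-based decision
engine — plus an audit worksheet and a validation harness.

The package deliberately replaces two production components with
reproducible analogues:

* the learned document-extraction model is replaced by a **deterministic
  pattern grammar** with a heuristic confidence score. The point is not to
  emulate a classifier's error profile but to exercise the same gating and
  decision logic with fully auditable behavior;
* the EHR itself is replaced by an **in-memory patient-snapshot table**
  (due date, frequency modifier, manual-assignment date, last documented
  colonoscopy, orders).

Pathology-driven interval logic is out of scope: the follow-up recommendation
stated in the colonoscopy report is taken as the source of truth, and
pathology reports simply route to human review.

## Extraction

**Document type** is scored by counting distinct lexicon hits — procedure
vocabulary (cecum, withdrawal, polypectomy, …) versus histology vocabulary
(specimen, microscopic, adenoma, …). Confidence is purity × saturation
(`winner/(hits_total) × min(1, winner/3)`); zero or tied evidence yields
OTHER at confidence 0. Document type does not enter the readiness gate; it
is recorded for audit.

**Result date.** Date tokens are scanned in three dialects — ISO, US
`MM/DD/YYYY`, and long-form English months; day-first dialects are rejected
(US health-system context). A date within 40 characters after a labeled
context ("procedure date", "date of procedure", "exam date", "date of
exam", "date of service") scores 0.95; conflicting labeled dates subtract
0.15 each (capped); a bare letterhead date falls back to 0.50, deliberately
below the gate — an unlabeled date should never drive an automated update.

**Follow-up recommendation.** An ordered grammar, first matching pattern
wins: negation ("no further surveillance …") → kind NONE; numeric range
("3-5 years", hyphen/en-dash/"to") → RANGE; single interval ("in 5 years",
"within 36 months") → INTERVAL; a date token preceded within 80 characters
by a recommendation cue (recommend, repeat, return, plan, follow-up,
surveillance, next, due) → EXPLICIT_DATE. All intervals are normalized to
months (`years × 12`) so the 10-year horizon rule compares one unit. Among
several matches of the winning pattern, the one nearest a cue wins, ties
broken toward the earlier resolved date (the conservative reading);
conflicting candidate values subtract 0.15. Cue-adjacent matches score
0.90, cue-less ones 0.60 (below the gate).

**Resolution and gate.** RANGE resolves to its earlier bound; month addition
clamps to the end of the target month (Feb 29 + 120 mo → Feb 28). A report
is RPA_READY iff a result date and a non-NONE recommendation are present
and `min(confidence_date, confidence_rec) > readiness_threshold` — strictly
greater, threshold default 0.70. The gate uses the minimum of the two
required field confidences; gating on an aggregate score would let one
strong field mask a weak one.

## Decision engine

Blocking rules are evaluated in a fixed precedence: identity/structural
failures first (E8 patient not found, E7 topic not assigned, E9 no matching
order), then data quality (E5 unassessable, E6 linked-date mismatch, STALE
report older than the last documented colonoscopy), then clinical guards
(E2 frequency modifier, E3 manual assignment after the procedure, E4 beyond
the 10-year horizon, E1 not earlier than the existing due date). The first
true rule is reported; the ordering surfaces the most fundamental blocker
and makes exception tallies deterministic.

Boundary choices, made once:

* **E1** compares dates, not intervals: a proposed due date equal to the
  existing one is suppressed as a no-op (reported as E1).
* **E4** is strict: exactly 10 years from the result date is allowed (it
  matches the system default interval); anything later is blocked.
* **E3** is strict: a manual assignment on the procedure date itself does
  not block; one day later does.
* **STALE** is audited under its own label rather than folded into a
  numbered exception, because operational tallies report "more recent
  procedure" as its own category.
* Order matching returns the most recent outstanding order placed on or
  before the linked procedure date; reports without a linked procedure date
  cannot match an order and block at E9.

Two independent implementations of the rules ship on purpose:
`evaluate()` (the production precedence chain, dateutil month arithmetic)
and `audit_predicates()` (a flat unconditional transcription with
hand-rolled calendar-clamp month addition). The corpus generator self-checks
every emitted scenario against the audit route, and the test suite holds a
third, test-local brute-force checker against which the engine is verified
on randomized inputs.

## Synthetic corpus

The generator emits report texts, snapshots and ground truth from a single
root seed fanned out per report index (`default_rng([seed, i])`), so any
subset regenerates identically and whole corpora are byte-stable.

Defaults are the generator's operating conditions, fixed up front:
document mix 90.6% colonoscopy / 6.7% pathology / 2.7% other; 57% of
colonoscopy reports carry a follow-up recommendation (the approximate
date-bearing share of a realistic inbound stream); intervals drawn from
{12, 36, 60, 84, 120} months — guideline-plausible surveillance values —
with 20% ranges and 10% explicit dates; the over-horizon scenario uses 156
months; the scenario mix is clean-dominated (0.65) with small weights on
each blocking rule. E5 carries weight 0 and requesting it is a
configuration error: the readiness gate guarantees an assessable follow-up
date before the engine runs, so no generable input can reach that branch.

Templates vary section headers, cue verbs, units (years/y/yr, months/mo)
and date dialects, but are enumerable by design: the grammar and the
templates are co-designed, which is what makes closed-loop recovery a
meaningful invariant (at noise 0, pipeline labels equal ground truth
exactly). `noise_level` corrupts the recommendation sentence of affected
reports (whitespace and digits destroyed, OCR-style), which the grammar is
documented to break on; the corruption draw is taken for every report
regardless of level, so corpora at different noise levels are coupled and
the not-ready fraction rises monotonically with noise.

What passing tests therefore show: the gate, rules, audit trail and metric
formulas behave exactly as specified on inputs whose phrasing the grammar
covers. What they do not show: recall on real clinical prose, whose
phrasing variety, OCR damage and missing elements are far beyond these
templates; the confidence scores are heuristic ranks, not calibrated
probabilities.

## Validation metrics

Each processed report maps to one of six outcome categories (correct
no-date deferral, missed date, inaccurate date, correct update, correct
exception, incorrect update). A ready report whose blocking code differs
from the expected one counts as an incorrect bot action. Accuracy is the
fraction of correct-update + correct-exception + correct-no-date reports;
the false-negative rate is missed dates over date-bearing reports (missed +
all gated reports, which carry an extracted date by construction).

Confidence intervals are Wald (normal approximation),
`p ± 1.96·sqrt(p(1−p)/n)`, computed via
`statsmodels.stats.proportion.proportion_confint(method="normal")`, each
reported with its own denominator. Note one known discrepancy in the
literature this mirrors: a published FN-rate interval of 29.4%–36.4% for
130/395 is consistent with a Wald interval computed on the full sample
(n = 690) rather than on the date-bearing denominator (n = 395, which gives
28.3%–37.5%); this package always uses the rate's own denominator and
documents the difference rather than reproducing it. Percentages are
rendered to one decimal place. A zero date-bearing denominator reports the
FN rate as undefined, never as zero.

`tally_from_counts` applies the same formulas to externally supplied count
tables (worked-example mode) without running the pipeline, so published
tallies can be audited independently.

## Problem sizes and numerical choices

The acceptance script uses a 2,000-report noise-free corpus for closed-loop
recovery and 10,000 randomized snapshot/extraction cases for engine/oracle
agreement — sizes chosen so binomial sampling error on the recovered mixture
proportions is small (3 standard errors ≈ 1–3 points) while the whole run
stays in seconds. Scenario-mix recovery is asserted within 3 binomial
standard errors of the configured weights. All randomness flows from
explicit integer seeds; there is none in extraction or decision logic.

## Limitations

* The grammar is a reconstruction of plausible recommendation phrasing, not
  an inventory of real-world variants; real corpora would require extending
  `phrase_grammar` (serialized in priority order precisely so that this is
  an auditable configuration change).
* Confidence scores are ordinal heuristics; the 0.70 gate is meaningful
  only relative to the score anchors documented above.
* The snapshot table models a single HM topic and ignores order creation,
  multi-topic interactions, and write-back concurrency.
* Patient identity comes from the manifest; no identity resolution from
  text is attempted.
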