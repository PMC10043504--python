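"""Event-based progression classification (first-vs-last beyond threshold).

An eye is eligible for a metric when it has at least two non-missing tests
of that metric and the last lies a year or more after the first.  The
baseline value (first test, or second test in the confirmation variant) is
fed through the fitted quantile line to obtain the event cutoff; the eye is
a statistical progressor when the last value lies *strictly* beyond the
cutoff in the worsening direction.  Equality with the cutoff is stable —
the threshold must be exceeded.
"""

from __future__ import annotations

from typing import Iterable

from .cohort import CohortDataset, EyeSeries, years_between
from .decision import Decision, DecisionTable, Status
from .metrics import Direction, get_metric, metric_names
from .thresholds import ThresholdBank

MIN_SPAN_DAYS = 365

COMPARISONS = ("first_vs_last", "second_vs_last")


def event_eligible(series: EyeSeries, metric: str) -> bool:
    """True iff >= 2 non-missing tests and last >= 365 days after first."""
    tests = series.metric_tests(metric)
    if len(tests) < 2:
        return False
    return (tests[-1][0] - tests[0][0]).days >= MIN_SPAN_DAYS


def classify_event(
    series: EyeSeries,
    metric: str,
    bank: ThresholdBank,
    tau: float = 0.025,
    comparison: str = "first_vs_last",
    *,
    paper_literal: bool = False,
) -> Decision:
    """Classify one eye for one metric against the threshold bank."""
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    if not event_eligible(series, metric):
        return Decision(series.eye_id, metric, Status.INELIGIBLE)

    model = bank.get(metric, tau)
    tests = series.metric_tests(metric)
    if comparison == "second_vs_last":
        if len(tests) < 3:
            return Decision(series.eye_id, metric, Status.UNDETERMINED)
        base_date, base_value = tests[1]
    else:
        base_date, base_value = tests[0]
    last_date, last_value = tests[-1]

    cutoff = model.threshold_at(base_value)
    direction = get_metric(metric).direction
    if direction == Direction.DECREASE or paper_literal:
        flagged = last_value < cutoff
    else:
        flagged = last_value > cutoff
    return Decision(
        eye_id=series.eye_id,
        name=metric,
        status=Status.PROGRESSING if flagged else Status.STABLE,
        baseline=base_value,
        comparison_value=last_value,
        cutoff=cutoff,
        dt_years=years_between(base_date, last_date),
    )


def classify_event_all(
    cohort: CohortDataset,
    bank: ThresholdBank,
    tau: float = 0.025,
    metrics: Iterable[str] | None = None,
    comparison: str = "first_vs_last",
    *,
    paper_literal: bool = False,
) -> DecisionTable:
    """One Decision per (eye, metric); input to composite rules and evaluation."""
    names = list(metrics) if metrics is not None else metric_names()
    table: DecisionTable = {}
    for eye in cohort:
        table[eye.eye_id] = {
            m: classify_event(eye, m, bank, tau, comparison, paper_literal=paper_literal)
            for m in names
        }
    return table
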