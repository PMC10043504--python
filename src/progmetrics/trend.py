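"""Trend-based progression classification (significant worsening OLS slope).

For each eligible series (at least four non-missing tests spanning a year
or more) the metric is regressed on time (years from the first test) by
ordinary least squares.  The one-tailed p-value is the Student-t
probability, on n - 2 degrees of freedom, of a slope this extreme in the
worsening direction: the lower tail for metrics that fall with damage, the
upper tail for PSD.  An eye progresses at level alpha when the slope lies
in the worsening direction and p < alpha (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .cohort import CohortDataset, EyeSeries, years_between
from .decision import Decision, DecisionTable, Status
from .metrics import Direction, get_metric, metric_names

MIN_TESTS = 4
MIN_SPAN_DAYS = 365

ALPHA_LEVELS = (0.05, 0.025, 0.01)


@dataclass
class TrendFit:
    """OLS fit of one metric's series against years from first test."""

    eye_id: str
    metric: str
    slope: float
    intercept: float
    se_slope: float
    t_stat: float
    p_one_tailed: float
    n_tests: int
    span_years: float
    degenerate: bool = False     # zero-residual (perfect) fit


def trend_eligible(series: EyeSeries, metric: str) -> bool:
    """True iff >= 4 non-missing tests spanning >= 365 days."""
    tests = series.metric_tests(metric)
    if len(tests) < MIN_TESTS:
        return False
    return (tests[-1][0] - tests[0][0]).days >= MIN_SPAN_DAYS


def fit_trend(
    series: EyeSeries, metric: str, *, paper_literal: bool = False
) -> TrendFit:
    """Closed-form OLS slope, standard error and one-tailed p for one series."""
    tests = series.metric_tests(metric)
    if len(tests) < MIN_TESTS:
        raise ValueError(
            f"eye {series.eye_id}, metric {metric}: {len(tests)} tests < {MIN_TESTS}"
        )
    t0 = tests[0][0]
    x = np.array([years_between(t0, d) for d, _ in tests])
    y = np.array([v for _, v in tests])
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError(f"eye {series.eye_id}: zero time variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    rss = float(np.sum(resid**2))
    dof = n - 2
    span = float(x[-1])

    direction = get_metric(metric).direction
    worsening_lower = direction == Direction.DECREASE or paper_literal

    scale = max(float(np.sum(y**2)), 1.0)
    if rss <= 1e-12 * scale:
        # Perfect fit: p degenerates to 0 / 0.5 / 1 by the slope's sign.
        if math.isclose(slope, 0.0, abs_tol=1e-12):
            p = 0.5
        elif (slope < 0) == worsening_lower:
            p = 0.0
        else:
            p = 1.0
        return TrendFit(series.eye_id, metric, slope, intercept, 0.0,
                        math.inf if p == 0.0 else 0.0, p, n, span, degenerate=True)

    se = math.sqrt(rss / dof / sxx)
    t_stat = slope / se
    if worsening_lower:
        p = float(stats.t.cdf(t_stat, dof))
    else:
        p = float(stats.t.sf(t_stat, dof))
    return TrendFit(series.eye_id, metric, slope, intercept, se, t_stat, p, n, span)


def classify_trend(fit: TrendFit, alpha: float = 0.05) -> Decision:
    """Progressing iff the slope worsens and p_one_tailed < alpha (strict)."""
    flagged = fit.p_one_tailed < alpha and fit.p_one_tailed < 0.5
    return Decision(
        eye_id=fit.eye_id,
        name=fit.metric,
        status=Status.PROGRESSING if flagged else Status.STABLE,
        dt_years=fit.span_years,
        slope=fit.slope,
        se_slope=fit.se_slope,
        p_value=fit.p_one_tailed,
    )


def classify_trend_all(
    cohort: CohortDataset,
    alpha: float = 0.05,
    metrics: Iterable[str] | None = None,
    *,
    paper_literal: bool = False,
) -> DecisionTable:
    """One Decision per (eye, metric) from the trend analysis."""
    names = list(metrics) if metrics is not None else metric_names()
    table: DecisionTable = {}
    for eye in cohort:
        row = {}
        for m in names:
            if not trend_eligible(eye, m):
                row[m] = Decision(eye.eye_id, m, Status.INELIGIBLE)
            else:
                row[m] = classify_trend(
                    fit_trend(eye, m, paper_literal=paper_literal), alpha
                )
        table[eye.eye_id] = row
    return table
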