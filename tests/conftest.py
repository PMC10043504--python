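import datetime as dt

import pytest

from progmetrics.cohort import CohortDataset, EyeSeries, Visit
from progmetrics.thresholds import ThresholdBank, ThresholdModel

BASE = dt.date(2021, 1, 4)


def series_from_points(
    points,
    metric="G_small",
    eye_id="E1",
    group="patient",
    dp_label="not_DP",
    fp=2.0,
    fl=5.0,
):
    """Build an EyeSeries from (day_offset, value) points for one metric."""
    visits = [
        Visit(BASE + dt.timedelta(days=int(d)), {metric: float(v)}, fp, fl)
        for d, v in points
    ]
    return EyeSeries(eye_id, group, dp_label, visits)


def multi_metric_series(points_by_metric, eye_id="E1", group="patient", dp_label="not_DP"):
    """Build an EyeSeries from {metric: [(day, value), ...]} maps."""
    by_day: dict[int, dict[str, float]] = {}
    for metric, pts in points_by_metric.items():
        for d, v in pts:
            by_day.setdefault(int(d), {})[metric] = float(v)
    visits = [
        Visit(BASE + dt.timedelta(days=d), vals, 2.0, 5.0)
        for d, vals in sorted(by_day.items())
    ]
    return EyeSeries(eye_id, group, dp_label, visits)


def identity_bank(metrics=("G_small",), taus=(0.025,), offset=0.0, slope=1.0):
    """Threshold bank whose cutoff is ``offset + slope * baseline``."""
    models = {
        (m, tau): ThresholdModel(m, tau, offset, slope, n_pairs=100)
        for m in metrics
        for tau in taus
    }
    return ThresholdBank(models)


@pytest.fixture
def two_eye_cohort():
    """One eligible patient eye and one eligible HC eye, single metric."""
    e1 = series_from_points([(0, 100.0), (200, 99.0), (420, 95.0)], eye_id="P1")
    e2 = series_from_points(
        [(0, 98.0), (400, 98.5)], eye_id="H1", group="HC", dp_label="not_DP"
    )
    return CohortDataset([e1, e2], provenance="fixture")
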