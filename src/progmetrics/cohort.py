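"""Longitudinal cohort containers and long-format CSV I/O.

A cohort is a list of eye series; each eye series is a dated sequence of
visits carrying a sparse map of summary-metric values plus the perimetry
reliability indices (false-positive rate, fixation-loss rate) used by the
visual-field quality filter.

The on-disk representation is a long-format CSV with one row per
(eye, visit date, metric) triple:

    eye_id,group,dp_label,visit_date,metric,value,vf_fp_rate_pct,vf_fixation_loss_pct

Dates are ISO-8601; internally all time arithmetic is in years from the
first visit (365.25-day years).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .metrics import builtin_metrics, get_metric

GROUPS = ("HC", "patient", "suspect")
DP_LABELS = ("DP", "not_DP", "unknown")

REQUIRED_COLUMNS = (
    "eye_id",
    "group",
    "dp_label",
    "visit_date",
    "metric",
    "value",
    "vf_fp_rate_pct",
    "vf_fixation_loss_pct",
)

#: VF reliability exclusion thresholds (strict inequalities).
VF_FP_LIMIT_PCT = 15.0
VF_FIXATION_LOSS_LIMIT_PCT = 33.0


def years_between(a: dt.date, b: dt.date) -> float:
    """Elapsed time from ``a`` to ``b`` in 365.25-day years; requires b >= a."""
    if b < a:
        raise ValueError(f"end date {b} precedes start date {a}")
    return (b - a).days / 365.25


@dataclass
class Visit:
    """One study visit: a date, a sparse metric→value map, reliability indices."""

    date: dt.date
    values: dict[str, float] = field(default_factory=dict)
    vf_fp_rate_pct: float | None = None
    vf_fixation_loss_pct: float | None = None

    @property
    def vf_pattern(self) -> str:
        """Which perimetry patterns contributed values: 24-2, 10-2, both or none."""
        has24 = any(get_metric(n).modality.value == "VF_24_2" for n in self.values)
        has10 = any(get_metric(n).modality.value == "VF_10_2" for n in self.values)
        if has24 and has10:
            return "both"
        if has24:
            return "24-2"
        if has10:
            return "10-2"
        return "none"


@dataclass
class EyeSeries:
    """One eye's visit series with its group and reference-standard label."""

    eye_id: str
    group: str
    dp_label: str = "unknown"
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"eye {self.eye_id}: bad group {self.group!r}")
        if self.dp_label not in DP_LABELS:
            raise ValueError(f"eye {self.eye_id}: bad dp_label {self.dp_label!r}")
        if self.dp_label == "DP" and self.group == "HC":
            raise ValueError(f"eye {self.eye_id}: DP label on a healthy-control eye")
        self.visits.sort(key=lambda v: v.date)
        dates = [v.date for v in self.visits]
        if len(set(dates)) != len(dates):
            raise ValueError(f"eye {self.eye_id}: duplicate visit dates")

    def metric_tests(self, metric: str) -> list[tuple[dt.date, float]]:
        """Dated non-missing measurements of one metric, in time order."""
        return [
            (v.date, v.values[metric]) for v in self.visits if metric in v.values
        ]

    @property
    def baseline_date(self) -> dt.date:
        if not self.visits:
            raise ValueError(f"eye {self.eye_id} has no visits")
        return self.visits[0].date


@dataclass
class CohortDataset:
    """A set of eye series plus a provenance tag (file path or generator seed)."""

    eyes: list[EyeSeries]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [e.eye_id for e in self.eyes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate eye_id in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.eyes)

    def __iter__(self):
        return iter(self.eyes)

    def get(self, eye_id: str) -> EyeSeries:
        for e in self.eyes:
            if e.eye_id == eye_id:
                return e
        raise KeyError(eye_id)

    def subset(self, groups: Iterable[str]) -> "CohortDataset":
        gs = set(groups)
        return CohortDataset(
            [e for e in self.eyes if e.group in gs],
            provenance=f"{self.provenance}|subset={sorted(gs)}",
        )


class Exclusion(NamedTuple):
    """One visual-field quality exclusion: which eye/visit and why."""

    eye_id: str
    visit_date: dt.date
    rule: str


def load_cohort(source) -> CohortDataset:
    """Read a long-format cohort CSV into a :class:`CohortDataset`.

    ``source`` is a path or open text buffer.  Unknown metric names and
    duplicate (eye, date, metric) rows are hard errors; rows with
    unparseable dates or values are rejected with their row numbers.
    """
    df = pd.read_csv(source, dtype={"eye_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")

    if len(df) == 0:
        return CohortDataset([], provenance=str(source))

    registry = builtin_metrics()
    unknown = sorted(set(df["metric"]) - set(registry))
    if unknown:
        raise KeyError(f"unknown metric name(s) in cohort CSV: {unknown}")

    dates = pd.to_datetime(df["visit_date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        # fallback: real month offsets from baseline instead of ISO dates
        months = pd.to_numeric(df["visit_date"], errors="coerce")
        if months.notna().all():
            epoch = dt.date(2020, 1, 6)
            dates = pd.Series(
                [
                    pd.Timestamp(epoch + dt.timedelta(days=round(m * 30.4375)))
                    for m in months
                ],
                index=df.index,
            )
        else:
            bad = df.index[dates.isna()].tolist()
            raise ValueError(f"unparseable visit_date at data row(s): {bad}")
    df = df.assign(_date=dates.dt.date)

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() & df["value"].notna()].tolist()
    if bad:
        raise ValueError(f"unparseable value at data row(s): {bad}")
    df = df.assign(_value=values)

    dup = df.duplicated(subset=["eye_id", "_date", "metric"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["eye_id", "visit_date", "metric"]].head(5)
        raise ValueError(
            "duplicate (eye, date, metric) rows, e.g.:\n" + rows.to_string(index=False)
        )

    eyes: list[EyeSeries] = []
    for eye_id, g in df.groupby("eye_id", sort=True):
        groups = g["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"eye {eye_id}: conflicting group labels {list(groups)}")
        labels = g["dp_label"].dropna().unique()
        if len(labels) > 1:
            raise ValueError(f"eye {eye_id}: conflicting dp_label {list(labels)}")
        dp_label = labels[0] if len(labels) else "unknown"

        visits = []
        for date, vg in g.groupby("_date", sort=True):
            vals = {
                m: float(v)
                for m, v in zip(vg["metric"], vg["_value"])
                if pd.notna(v)
            }
            fp = vg["vf_fp_rate_pct"].dropna()
            fl = vg["vf_fixation_loss_pct"].dropna()
            visits.append(
                Visit(
                    date=date,
                    values=vals,
                    vf_fp_rate_pct=float(fp.iloc[0]) if len(fp) else None,
                    vf_fixation_loss_pct=float(fl.iloc[0]) if len(fl) else None,
                )
            )
        eyes.append(EyeSeries(str(eye_id), str(groups[0]), str(dp_label), visits))

    return CohortDataset(eyes, provenance=str(source))


def cohort_to_frame(cohort: CohortDataset) -> pd.DataFrame:
    """Long-format DataFrame view of a cohort (one row per eye/date/metric)."""
    rows = []
    for eye in cohort:
        for v in eye.visits:
            for m, x in sorted(v.values.items()):
                rows.append(
                    {
                        "eye_id": eye.eye_id,
                        "group": eye.group,
                        "dp_label": eye.dp_label,
                        "visit_date": v.date.isoformat(),
                        "metric": m,
                        "value": round(float(x), 4),
                        "vf_fp_rate_pct": None
                        if v.vf_fp_rate_pct is None
                        else round(float(v.vf_fp_rate_pct), 2),
                        "vf_fixation_loss_pct": None
                        if v.vf_fixation_loss_pct is None
                        else round(float(v.vf_fixation_loss_pct), 2),
                    }
                )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_cohort(cohort: CohortDataset, dest) -> None:
    """Write a cohort as long-format CSV (values rounded to 4 decimals)."""
    cohort_to_frame(cohort).to_csv(dest, index=False)


def apply_vf_quality_filter(
    cohort: CohortDataset,
) -> tuple[CohortDataset, list[Exclusion]]:
    """Drop VF values from unreliable visits (FP > 15% or fixation loss > 33%).

    OCT values are untouched.  Returns the filtered cohort and a log of
    (eye, visit date, rule) exclusions.  Idempotent.
    """
    vf_names = {n for n, m in builtin_metrics().items() if m.is_vf}
    log: list[Exclusion] = []
    new_eyes = []
    for eye in cohort:
        new_visits = []
        for v in eye.visits:
            rules = []
            if v.vf_fp_rate_pct is not None and v.vf_fp_rate_pct > VF_FP_LIMIT_PCT:
                rules.append("fp_gt_15")
            if (
                v.vf_fixation_loss_pct is not None
                and v.vf_fixation_loss_pct > VF_FIXATION_LOSS_LIMIT_PCT
            ):
                rules.append("fixation_loss_gt_33")
            has_vf = any(m in vf_names for m in v.values)
            if rules and has_vf:
                vals = {m: x for m, x in v.values.items() if m not in vf_names}
                for rule in rules:
                    log.append(Exclusion(eye.eye_id, v.date, rule))
                new_visits.append(
                    Visit(v.date, vals, v.vf_fp_rate_pct, v.vf_fixation_loss_pct)
                )
            else:
                new_visits.append(
                    Visit(v.date, dict(v.values), v.vf_fp_rate_pct, v.vf_fixation_loss_pct)
                )
        new_eyes.append(EyeSeries(eye.eye_id, eye.group, eye.dp_label, new_visits))
    return (
        CohortDataset(new_eyes, provenance=f"{cohort.provenance}|vf_quality_filtered"),
        log,
    )


def exclusions_to_frame(log: list[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"eye_id": e.eye_id, "visit_date": e.visit_date.isoformat(), "rule": e.rule}
            for e in log
        ],
        columns=["eye_id", "visit_date", "rule"],
    )


def merge_paired_visits(cohort: CohortDataset, window_days: int = 45) -> CohortDataset:
    """Merge a VF-only visit into a nearby OCT visit within ``window_days``.

    Real series occasionally acquire OCT and perimetry on different dates;
    this pairs such split visits onto the earlier (OCT) date.  Values never
    overwrite an existing entry.  Synthetic cohorts acquire everything on
    one date, so this is a no-op for them.
    """
    vf_names = {n for n, m in builtin_metrics().items() if m.is_vf}
    new_eyes = []
    for eye in cohort:
        merged: list[Visit] = []
        for v in sorted(eye.visits, key=lambda x: x.date):
            vf_only = v.values and all(m in vf_names for m in v.values)
            target = None
            if vf_only and merged:
                prev = merged[-1]
                if (v.date - prev.date).days <= window_days and any(
                    m not in vf_names for m in prev.values
                ):
                    target = prev
            if target is not None:
                for m, x in v.values.items():
                    target.values.setdefault(m, x)
                if target.vf_fp_rate_pct is None:
                    target.vf_fp_rate_pct = v.vf_fp_rate_pct
                if target.vf_fixation_loss_pct is None:
                    target.vf_fixation_loss_pct = v.vf_fixation_loss_pct
            else:
                merged.append(
                    Visit(v.date, dict(v.values), v.vf_fp_rate_pct, v.vf_fixation_loss_pct)
                )
        new_eyes.append(EyeSeries(eye.eye_id, eye.group, eye.dp_label, merged))
    return CohortDataset(new_eyes, provenance=f"{cohort.provenance}|merged")
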