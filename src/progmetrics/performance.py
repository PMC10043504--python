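"""Specificity, sensitivity, precision and bootstrap confidence intervals.

Specificity is judged against the healthy-control (HC) group: an HC eye
flagged as progressing is a false positive.  Sensitivity is judged against
the definitely-progressing (DP) reference eyes: a DP eye flagged is a true
positive.  Precision is the fraction of flagged patient eyes confirmed DP.
Percentages are rounded half-up to integers; 95% confidence intervals come
from a percentile bootstrap — 1000 resamples of equal size drawn with
replacement within the reference group, with the empirical 2.5th/97.5th
order statistics (rank ceil(0.025*B) and ceil(0.975*B), no interpolation).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .decision import Status

DEFAULT_BOOTSTRAP_B = 1000


@dataclass
class Counts:
    """Confusion counts of one metric/rule against the reference groups."""

    fp: int                   # HC eyes flagged progressing
    n_hc: int
    tp: int                   # DP eyes flagged progressing
    n_dp: int
    n_patients_flagged: int   # non-HC eyes flagged progressing


@dataclass
class PerformanceRow:
    """One row of a study-style performance table (counts, %, 95% CIs)."""

    name: str
    n_hc: int
    fp: int
    specificity_pct: int | None
    spec_ci: tuple[int, int] | None
    n_patients_flagged: int
    n_dp: int
    tp: int
    sensitivity_pct: int | None
    sens_ci: tuple[int, int] | None
    precision_pct: int | None


def _flagged(status: Status) -> bool:
    # undetermined/ineligible count as "not flagged"
    return status == Status.PROGRESSING


def confusion_counts(
    statuses: Mapping[str, Status], cohort: CohortDataset
) -> Counts:
    """Count FPs among HC eyes and TPs among DP eyes for one metric/rule."""
    fp = n_hc = tp = n_dp = n_pat_flag = 0
    for eye in cohort:
        s = statuses.get(eye.eye_id)
        flag = s is not None and _flagged(s)
        if eye.group == "HC":
            n_hc += 1
            fp += flag
        else:
            n_pat_flag += flag
            if eye.dp_label == "DP":
                n_dp += 1
                tp += flag
    return Counts(fp, n_hc, tp, n_dp, n_pat_flag)


def proportion_pct(numerator: int, denominator: int) -> int | None:
    """Integer percentage under the reporting convention; None for zero denominator.

    Rounds half-up in two stages — first to one decimal percent, then to the
    integer — matching how the reported tables round (e.g. 13/17 = 76.47%
    appears as 77 via 76.5, while 11/17 = 64.71% appears as 65).
    """
    if denominator == 0:
        return None
    tenths = math.floor(Fraction(1000 * numerator, denominator) + Fraction(1, 2))
    return math.floor(Fraction(tenths, 10) + Fraction(1, 2))


def bootstrap_ci(
    outcomes: Sequence[int],
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[int, int]:
    """Percentile-bootstrap 95% CI (integer percents) for a binary proportion.

    Draws ``B`` resamples of size n with replacement and takes the
    empirical 2.5th/97.5th order statistics of the resampled proportions
    (ranks ceil(0.025 B) and ceil(0.975 B)), each converted via
    :func:`proportion_pct`.  Deterministic given the seed.
    """
    arr = np.asarray(outcomes, dtype=np.int64)
    n = arr.size
    if n == 0:
        raise ValueError("bootstrap_ci requires at least one outcome")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    successes = np.sort(arr[idx].sum(axis=1))
    lo_k = successes[math.ceil(0.025 * B) - 1]
    hi_k = successes[math.ceil(0.975 * B) - 1]
    return proportion_pct(int(lo_k), n), proportion_pct(int(hi_k), n)


def _row_seed(master_seed: int, name: str, which: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=int(master_seed) % 2**31,
        spawn_key=(zlib.crc32(f"{name}|{which}".encode("utf-8")),),
    )


def performance_row(
    name: str,
    statuses: Mapping[str, Status],
    cohort: CohortDataset,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
) -> PerformanceRow:
    """Assemble counts, rounded percentages and bootstrap CIs for one name."""
    c = confusion_counts(statuses, cohort)

    spec_pct = spec_ci = None
    if c.n_hc > 0:
        spec_outcomes = []
        for eye in cohort:
            if eye.group == "HC":
                s = statuses.get(eye.eye_id)
                spec_outcomes.append(0 if (s is not None and _flagged(s)) else 1)
        spec_pct = proportion_pct(c.n_hc - c.fp, c.n_hc)
        spec_ci = bootstrap_ci(spec_outcomes, B, _row_seed(seed, name, "spec"))

    sens_pct = sens_ci = None
    if c.n_dp > 0:
        sens_outcomes = []
        for eye in cohort:
            if eye.group != "HC" and eye.dp_label == "DP":
                s = statuses.get(eye.eye_id)
                sens_outcomes.append(1 if (s is not None and _flagged(s)) else 0)
        sens_pct = proportion_pct(c.tp, c.n_dp)
        sens_ci = bootstrap_ci(sens_outcomes, B, _row_seed(seed, name, "sens"))

    precision_pct = (
        proportion_pct(c.tp, c.n_patients_flagged) if c.n_patients_flagged > 0 else None
    )
    return PerformanceRow(
        name=name,
        n_hc=c.n_hc,
        fp=c.fp,
        specificity_pct=spec_pct,
        spec_ci=spec_ci,
        n_patients_flagged=c.n_patients_flagged,
        n_dp=c.n_dp,
        tp=c.tp,
        sensitivity_pct=sens_pct,
        sens_ci=sens_ci,
        precision_pct=precision_pct,
    )


def performance_table(
    status_maps: Mapping[str, Mapping[str, Status]],
    cohort: CohortDataset,
    names: Iterable[str] | None = None,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
) -> pd.DataFrame:
    """One performance row per requested metric/rule name.

    Names without decisions are omitted with a warning.
    """
    wanted = list(names) if names is not None else list(status_maps)
    rows = []
    for name in wanted:
        if name not in status_maps:
            warnings.warn(f"no decisions for {name!r}; row omitted", stacklevel=2)
            continue
        r = performance_row(name, status_maps[name], cohort, B, seed)
        rows.append(
            {
                "name": r.name,
                "n_hc": r.n_hc,
                "fp": r.fp,
                "specificity_pct": r.specificity_pct,
                "spec_ci_lo": None if r.spec_ci is None else r.spec_ci[0],
                "spec_ci_hi": None if r.spec_ci is None else r.spec_ci[1],
                "n_patients_flagged": r.n_patients_flagged,
                "n_dp": r.n_dp,
                "tp": r.tp,
                "sensitivity_pct": r.sensitivity_pct,
                "sens_ci_lo": None if r.sens_ci is None else r.sens_ci[0],
                "sens_ci_hi": None if r.sens_ci is None else r.sens_ci[1],
                "precision_pct": r.precision_pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "n_hc", "fp", "specificity_pct", "spec_ci_lo", "spec_ci_hi",
            "n_patients_flagged", "n_dp", "tp", "sensitivity_pct",
            "sens_ci_lo", "sens_ci_hi", "precision_pct",
        ],
    )


def fp_comparison_table(
    trend_maps: Mapping[str, Mapping[str, Status]],
    event_maps: Mapping[str, Mapping[str, Status]],
    cohort: CohortDataset,
    names: Iterable[str],
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
) -> pd.DataFrame:
    """Side-by-side trend vs event false-positive counts and specificities."""
    rows = []
    for name in names:
        if name not in trend_maps or name not in event_maps:
            warnings.warn(f"no paired decisions for {name!r}; row omitted", stacklevel=2)
            continue
        tr = performance_row(name, trend_maps[name], cohort, B, seed)
        ev = performance_row(name, event_maps[name], cohort, B, seed)
        rows.append(
            {
                "name": name,
                "n_hc": tr.n_hc,
                "trend_fp": tr.fp,
                "trend_specificity_pct": tr.specificity_pct,
                "trend_spec_ci_lo": None if tr.spec_ci is None else tr.spec_ci[0],
                "trend_spec_ci_hi": None if tr.spec_ci is None else tr.spec_ci[1],
                "event_fp": ev.fp,
                "event_specificity_pct": ev.specificity_pct,
                "event_spec_ci_lo": None if ev.spec_ci is None else ev.spec_ci[0],
                "event_spec_ci_hi": None if ev.spec_ci is None else ev.spec_ci[1],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "n_hc", "trend_fp", "trend_specificity_pct",
            "trend_spec_ci_lo", "trend_spec_ci_hi", "event_fp",
            "event_specificity_pct", "event_spec_ci_lo", "event_spec_ci_hi",
        ],
    )
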