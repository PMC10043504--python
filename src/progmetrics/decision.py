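"""Per-eye classification outcomes shared by the event and trend analyses."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd


class Status(str, Enum):
    PROGRESSING = "progressing"
    STABLE = "stable"
    INELIGIBLE = "ineligible"         # series fails the eligibility rule
    UNDETERMINED = "undetermined"     # a required measurement is missing


@dataclass
class Decision:
    """Classification of one eye for one metric or composite rule.

    ``baseline``/``comparison_value``/``cutoff`` are filled by the event
    analysis; ``slope``/``se_slope``/``p_value`` by the trend analysis.
    """

    eye_id: str
    name: str
    status: Status
    baseline: float | None = None
    comparison_value: float | None = None
    cutoff: float | None = None
    dt_years: float | None = None
    slope: float | None = None
    se_slope: float | None = None
    p_value: float | None = None

    @property
    def flagged(self) -> bool:
        return self.status == Status.PROGRESSING


#: eye_id -> name -> Decision
DecisionTable = dict[str, dict[str, Decision]]


def status_map(table: DecisionTable, name: str) -> dict[str, Status]:
    """Per-eye status for one metric/rule column of a decision table."""
    return {eye: decs[name].status for eye, decs in table.items() if name in decs}


def decisions_to_frame(table: DecisionTable) -> pd.DataFrame:
    rows = []
    for eye_id in sorted(table):
        for name, d in sorted(table[eye_id].items()):
            rows.append(
                {
                    "eye_id": d.eye_id,
                    "name": d.name,
                    "status": d.status.value,
                    "baseline": d.baseline,
                    "comparison_value": d.comparison_value,
                    "cutoff": d.cutoff,
                    "dt_years": d.dt_years,
                    "slope": d.slope,
                    "se_slope": d.se_slope,
                    "p_value": d.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "eye_id", "name", "status", "baseline", "comparison_value",
            "cutoff", "dt_years", "slope", "se_slope", "p_value",
        ],
    )


def frame_to_status_maps(df: pd.DataFrame) -> dict[str, dict[str, Status]]:
    """Invert a decisions CSV into per-name status maps (name -> eye -> status)."""
    out: dict[str, dict[str, Status]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.name), {})[str(row.eye_id)] = Status(row.status)
    return out


def table_from_frame(df: pd.DataFrame) -> DecisionTable:
    table: DecisionTable = {}
    for row in df.itertuples(index=False):
        d = Decision(
            eye_id=str(row.eye_id),
            name=str(row.name),
            status=Status(row.status),
            baseline=None if pd.isna(row.baseline) else float(row.baseline),
            comparison_value=None if pd.isna(row.comparison_value) else float(row.comparison_value),
            cutoff=None if pd.isna(row.cutoff) else float(row.cutoff),
            dt_years=None if pd.isna(row.dt_years) else float(row.dt_years),
            slope=None if pd.isna(row.slope) else float(row.slope),
            se_slope=None if pd.isna(row.se_slope) else float(row.se_slope),
            p_value=None if pd.isna(row.p_value) else float(row.p_value),
        )
        table.setdefault(d.eye_id, {})[d.name] = d
    return table


def merge_tables(*tables: DecisionTable) -> DecisionTable:
    out: DecisionTable = {}
    for t in tables:
        for eye, decs in t.items():
            out.setdefault(eye, {}).update(decs)
    return out


StatusLike = Mapping[str, Status]
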