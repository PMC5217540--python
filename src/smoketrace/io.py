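"""CSV readers and writers for events, surveys, demographics and tables.

All files are UTF-8 CSV with a header row and ISO-8601 dates.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from smoketrace.agreement import STATUS_ORDER, AgreementTable, SurveyResponse
from smoketrace.algorithm import CollapsedStatus
from smoketrace.timeline import CodedEvent

__all__ = [
    "read_events_csv",
    "read_surveys_csv",
    "read_demographics_csv",
    "write_table_csv",
    "read_table_csv",
]


def _parse_date(value: str, context: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"{context}: invalid ISO-8601 date {value!r}") from exc


def read_events_csv(path: Union[str, Path]) -> dict[str, list[CodedEvent]]:
    """Read coded events grouped by patient.

    Expects columns ``patient_id,event_date,code,value`` (value may be
    blank).  Malformed rows are reported with their line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["patient_id", "event_date", "code"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} missing columns: {missing}")
    out: dict[str, list[CodedEvent]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        date = _parse_date(row.event_date, f"{path}:{lineno}")
        raw = getattr(row, "value", "")
        value = float(raw) if raw not in ("", None) else None
        out.setdefault(row.patient_id, []).append(
            CodedEvent(row.patient_id, date, row.code, value)
        )
    return out


def read_surveys_csv(path: Union[str, Path]) -> list[SurveyResponse]:
    """Read survey responses: ``patient_id,survey_date`` plus ``item``
    (1-5) and/or ``status`` (missing/smoker/ex_smoker/never_smoker)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["patient_id", "survey_date"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} missing columns: {missing}")
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        date = _parse_date(row.survey_date, f"{path}:{lineno}")
        raw_item = getattr(row, "item", "")
        item = int(float(raw_item)) if raw_item not in ("", None) else None
        raw_status = getattr(row, "status", "")
        status = CollapsedStatus(raw_status) if raw_status else None
        out.append(SurveyResponse(row.patient_id, date, item=item, status=status))
    return out


def read_demographics_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read ``patient_id,birth_date,sex``; dates validated as ISO-8601."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ["patient_id", "birth_date", "sex"] if c not in df.columns]
    if missing:
        raise ValueError(f"demographics file {path} missing columns: {missing}")
    df = df.copy()
    df["birth_date"] = [
        _parse_date(v, f"{path}:{i}") for i, v in enumerate(df["birth_date"], start=2)
    ]
    return df


def write_table_csv(
    table: AgreementTable,
    path: Union[str, Path],
    suppress_small_counts: bool = False,
) -> None:
    """Write a labelled 4x4 agreement table (rows GP, columns survey)."""
    df = table.to_dataframe(suppress_small_counts=suppress_small_counts)
    df.index.name = "gp_status"
    df.to_csv(path)


def read_table_csv(path: Union[str, Path]) -> AgreementTable:
    """Read a table written by :func:`write_table_csv` (no suppression)."""
    df = pd.read_csv(path, index_col=0)
    labels = [s.value for s in STATUS_ORDER]
    try:
        counts = df.loc[labels, labels].to_numpy(dtype=np.int64)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"table {path} must use labels {labels} on both axes") from exc
    return AgreementTable(counts)
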