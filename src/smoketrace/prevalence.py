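"""Annual smoking prevalence from classified GP records.

Patients aged 16 and over at a mid-year census date are classified with
the full life-course algorithm; relapsed and likely smokers count as
smokers.  By default the denominator is patients with a known (non-missing)
collapsed status; the registered-population denominator (missing included)
is available because published GP-side series do not always state which
was used.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from smoketrace.algorithm import CollapsedStatus, classify_full, collapse
from smoketrace.codelist import CodeRegistry
from smoketrace.timeline import CodedEvent, summarize_patient

__all__ = ["PrevalenceEstimate", "annual_prevalence", "prevalence_series"]


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Smoking prevalence for one year and stratum (``sex=None`` = overall)."""

    year: int
    sex: Optional[str]
    n_smokers: int
    n_classified: int
    denominator: str  # "classified" or "all"

    def __post_init__(self) -> None:
        if self.n_smokers > self.n_classified:
            raise ValueError("n_smokers cannot exceed n_classified")

    @property
    def prevalence(self) -> Optional[float]:
        if self.n_classified == 0:
            return None
        return self.n_smokers / self.n_classified


def _add_years(date: dt.date, years: int) -> dt.date:
    try:
        return date.replace(year=date.year + years)
    except ValueError:  # Feb 29
        return date.replace(year=date.year + years, day=28)


def annual_prevalence(
    events_by_patient: Mapping[str, Sequence[CodedEvent]],
    demographics: pd.DataFrame,
    registry: CodeRegistry,
    year: int,
    census_month_day: tuple[int, int] = (7, 1),
    include_missing: bool = False,
) -> list[PrevalenceEstimate]:
    """Smoking prevalence at a within-year census date, by sex and overall.

    ``demographics`` needs columns ``patient_id``, ``birth_date``
    (ISO-8601 or date) and ``sex``.  Patients under 16 at the census date
    are excluded from numerator and denominator.  With ``include_missing``
    the denominator is everyone aged 16+, otherwise only those with a
    known collapsed status.  Returns one estimate per sex present plus the
    overall row (``sex=None``), in deterministic order.
    """
    census = dt.date(year, *census_month_day)
    demo = demographics.copy()
    demo["birth_date"] = pd.to_datetime(demo["birth_date"]).dt.date

    by_sex: dict[Optional[str], list[CollapsedStatus]] = {}
    for row in demo.itertuples(index=False):
        if _add_years(row.birth_date, 16) > census:
            continue
        events = events_by_patient.get(row.patient_id, [])
        status = collapse(classify_full(summarize_patient(events, registry), census))
        by_sex.setdefault(str(row.sex), []).append(status)
        by_sex.setdefault(None, []).append(status)

    denominator = "all" if include_missing else "classified"
    estimates = []
    strata = sorted((s for s in by_sex if s is not None)) + [None]
    for sex in strata:
        statuses = by_sex.get(sex, [])
        if not include_missing:
            statuses = [s for s in statuses if s is not CollapsedStatus.MISSING]
        n_smokers = sum(1 for s in statuses if s is CollapsedStatus.SMOKER)
        estimates.append(
            PrevalenceEstimate(
                year=year,
                sex=sex,
                n_smokers=n_smokers,
                n_classified=len(statuses),
                denominator=denominator,
            )
        )
    return estimates


def prevalence_series(
    events_by_patient: Mapping[str, Sequence[CodedEvent]],
    demographics: pd.DataFrame,
    registry: CodeRegistry,
    from_year: int,
    to_year: int,
    **kwargs,
) -> list[PrevalenceEstimate]:
    """Annual prevalence for every year in [from_year, to_year]."""
    out: list[PrevalenceEstimate] = []
    for year in range(from_year, to_year + 1):
        out.extend(
            annual_prevalence(events_by_patient, demographics, registry, year, **kwargs)
        )
    return out
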