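"""End-to-end analyses binding timeline, classifier and agreement stages."""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence, Union

from smoketrace.agreement import (
    AgreementTable,
    KappaResult,
    Proportion,
    SurveyResponse,
    build_agreement_table,
    cohen_kappa,
    collapse_two_status,
    complete_pairs,
    discordance_summary,
)
from smoketrace.algorithm import (
    CollapsedStatus,
    SmokingStatus,
    classify_full,
    classify_nearest,
    classify_no_temporal,
    collapse,
)
from smoketrace.codelist import CodeRegistry
from smoketrace.timeline import CodedEvent, informative_events, summarize_patient

__all__ = ["VARIANTS", "classify_cohort", "ComparisonResult", "run_comparison"]

logger = logging.getLogger("smoketrace")

VARIANTS = ("full", "no-temporal", "nearest")

CensusSource = Union[dt.date, Callable[[str], dt.date]]


def _census_for(census: CensusSource, patient_id: str) -> dt.date:
    return census(patient_id) if callable(census) else census


def classify_cohort(
    events_by_patient: Mapping[str, Sequence[CodedEvent]],
    registry: CodeRegistry,
    census: CensusSource,
    variant: str = "full",
) -> dict[str, Union[SmokingStatus, CollapsedStatus]]:
    """Classify every patient at their census date under one variant.

    ``census`` is a fixed date or a per-patient callable (e.g. each
    person's survey date).  The ``nearest`` variant returns collapsed
    statuses directly; the others return the seven-level status.
    Patients are processed in sorted order so output is deterministic.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    out: dict[str, Union[SmokingStatus, CollapsedStatus]] = {}
    for pid in sorted(events_by_patient):
        events = events_by_patient[pid]
        date = _census_for(census, pid)
        if variant == "nearest":
            status_events = informative_events(events, registry, status_only=True)
            out[pid] = classify_nearest(status_events, date)
        else:
            summary = summarize_patient(events, registry)
            fn = classify_full if variant == "full" else classify_no_temporal
            out[pid] = fn(summary, date)
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement analysis of one classification variant against a survey."""

    variant: str
    table: AgreementTable
    kappa_two_status: KappaResult
    kappa_three_status: KappaResult
    discordance: dict[str, Proportion]


def run_comparison(
    events_by_patient: Mapping[str, Sequence[CodedEvent]],
    registry: CodeRegistry,
    surveys: Iterable[SurveyResponse],
    variant: str = "full",
) -> ComparisonResult:
    """Classify each surveyed patient at their own survey date and compare.

    Pipeline: timeline summary -> variant classifier -> collapse ->
    contingency table -> kappa (two- and three-status, complete pairs
    only) and discordance proportions.
    """
    surveys = list(surveys)
    survey_dates = {s.patient_id: s.survey_date for s in surveys}
    if len(survey_dates) != len(surveys):
        raise ValueError("duplicate patient in survey list")
    cohort_events = {
        pid: events_by_patient.get(pid, []) for pid in survey_dates
    }
    statuses = classify_cohort(
        cohort_events, registry, lambda pid: survey_dates[pid], variant
    )
    collapsed = {
        pid: st if isinstance(st, CollapsedStatus) else collapse(st)
        for pid, st in statuses.items()
    }

    n_with_events = sum(1 for pid in survey_dates if events_by_patient.get(pid))
    n_classified = sum(
        1 for st in collapsed.values() if st is not CollapsedStatus.MISSING
    )
    logger.info(
        "comparison (%s): %d surveyed, %d with GP events, %d with classifiable status",
        variant,
        len(surveys),
        n_with_events,
        n_classified,
    )

    table = build_agreement_table(collapsed, surveys)
    grid3 = complete_pairs(table)
    return ComparisonResult(
        variant=variant,
        table=table,
        kappa_two_status=cohen_kappa(collapse_two_status(grid3)),
        kappa_three_status=cohen_kappa(grid3),
        discordance=discordance_summary(table),
    )
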