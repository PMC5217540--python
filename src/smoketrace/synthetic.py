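"""Synthetic cohort generator: smoking life courses and their observation.

Real evaluation of the classifier used protected person-level record
linkage, so this module fabricates what that study observed: each person
follows a yearly two-state (smoking / quit) chain after a Bernoulli
initiation in adolescence, their GP sporadically records codes consistent
with the current true state (smokers sometimes via therapy or
administration codes rather than status codes), and a survey self-report
is taken in a fixed year, with ex-smokers sometimes claiming never to
have smoked — the dominant misclassification seen when GP histories are
compared with surveys.

The generator is deterministic given its seed: one root seed spawns a
substream per patient, so regenerating any patient is stable under
changes to cohort size.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from smoketrace.agreement import SurveyResponse
from smoketrace.algorithm import CollapsedStatus
from smoketrace.codelist import Category, CodeKind, CodeRegistry, default_registry
from smoketrace.timeline import CodedEvent

__all__ = ["CohortParams", "TruthRecord", "SyntheticCohort", "generate_cohort", "write_cohort"]

_TRUTH_TO_COLLAPSED = {
    Category.NEVER: CollapsedStatus.NEVER_SMOKER,
    Category.EX: CollapsedStatus.EX_SMOKER,
    Category.SMOKER: CollapsedStatus.SMOKER,
}

_STATUS_TO_ITEMS = {
    CollapsedStatus.SMOKER: (1, 2),
    CollapsedStatus.EX_SMOKER: (3, 4),
    CollapsedStatus.NEVER_SMOKER: (5, 5),
}


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for one synthetic cohort.

    Defaults describe a UK-like adult population surveyed in 2013:
    half ever smoke, starting between 14 and 25; smokers quit at 4%/year
    and ex-smokers relapse at 2%/year; patients see their GP about three
    times a year and roughly one visit in five leaves a smoking code;
    among smokers' codes, 15% are therapy/administration rather than
    status codes; a quarter of true ex-smokers self-report "never" at
    survey.
    """

    n_patients: int = 2000
    seed: int = 0
    initiation_prob: float = 0.5
    initiation_age: tuple[int, int] = (14, 25)
    annual_quit_prob: float = 0.04
    annual_relapse_prob: float = 0.02
    visit_rate: float = 3.0
    record_prob: float = 0.2
    therapy_code_prob: float = 0.15
    never_misreport_prob: float = 0.25
    smoker_misreport_prob: float = 0.0
    survey_year: int = 2013
    age_range: tuple[int, int] = (16, 84)
    records_start_year: int = 2000
    records_end_year: int = 2015

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "initiation_prob",
            "annual_quit_prob",
            "annual_relapse_prob",
            "record_prob",
            "therapy_code_prob",
            "never_misreport_prob",
            "smoker_misreport_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if self.visit_rate < 0:
            raise ValueError("visit_rate must be nonnegative")
        if self.initiation_age[0] > self.initiation_age[1]:
            raise ValueError("initiation_age bounds out of order")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range bounds out of order")


@dataclass(frozen=True)
class TruthRecord:
    """One patient's true life course, at yearly resolution.

    ``yearly[a]`` is the true state at age ``a``; a path starts NEVER and,
    once smoking is initiated, alternates only between SMOKER and EX.
    """

    patient_id: str
    birth_date: dt.date
    sex: str
    yearly: tuple[Category, ...]

    def true_status_at(self, date: dt.date) -> Category:
        age = date.year - self.birth_date.year
        age = min(max(age, 0), len(self.yearly) - 1)
        return self.yearly[age]


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated events, survey responses and ground truth."""

    params: CohortParams
    events: list[CodedEvent]
    surveys: list[SurveyResponse]
    truth: list[TruthRecord]

    def events_by_patient(self) -> dict[str, list[CodedEvent]]:
        out: dict[str, list[CodedEvent]] = {t.patient_id: [] for t in self.truth}
        for ev in self.events:
            out.setdefault(ev.patient_id, []).append(ev)
        return out

    def true_collapsed_at_survey(self) -> dict[str, CollapsedStatus]:
        """Ground-truth status at each patient's survey date, on the 4-level scale."""
        truth_by_id = {t.patient_id: t for t in self.truth}
        return {
            s.patient_id: _TRUTH_TO_COLLAPSED[
                truth_by_id[s.patient_id].true_status_at(s.survey_date)
            ]
            for s in self.surveys
        }


def _code_pools(registry: CodeRegistry) -> dict[str, list[str]]:
    status_kinds = (CodeKind.STATUS, CodeKind.INTENSITY)
    pools = {
        "never": [c for k in status_kinds for c in registry.codes(Category.NEVER, k)],
        "ex": [c for k in status_kinds for c in registry.codes(Category.EX, k)],
        "smoker_status": [
            c for k in status_kinds for c in registry.codes(Category.SMOKER, k)
        ],
        "smoker_therapy": [
            c
            for k in (CodeKind.THERAPY, CodeKind.CESSATION_ADMIN, CodeKind.ADVICE)
            for c in registry.codes(Category.SMOKER, k)
        ],
        "parent": registry.codes(kind=CodeKind.PARENT),
    }
    for name in ("never", "ex", "smoker_status"):
        if not pools[name]:
            raise ValueError(f"registry has no usable codes in pool {name!r}")
    return pools


def _life_course(params: CohortParams, rng: np.random.Generator, n_years: int) -> tuple[Category, ...]:
    ever = rng.random() < params.initiation_prob
    lo, hi = params.initiation_age
    init_age = int(rng.integers(lo, hi + 1)) if ever else None
    states: list[Category] = []
    state = Category.NEVER
    for age in range(n_years):
        if init_age is not None and age == init_age:
            state = Category.SMOKER
        elif state is Category.SMOKER and rng.random() < params.annual_quit_prob:
            state = Category.EX
        elif state is Category.EX and rng.random() < params.annual_relapse_prob:
            state = Category.SMOKER
        states.append(state)
    return tuple(states)


def _random_date_in_year(rng: np.random.Generator, year: int) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))


def generate_cohort(
    params: CohortParams, registry: Optional[CodeRegistry] = None
) -> SyntheticCohort:
    """Generate one cohort of events, survey responses and ground truth.

    Per patient: a Bernoulli smoking initiation followed by a yearly
    quit/relapse chain; GP visits drawn Poisson per calendar year from age
    16 (within the recording window), each leaving a smoking code with
    ``record_prob``, the code drawn from the registry pool matching the
    current true state; a survey self-report in ``survey_year`` equal to
    the true state except for ex->never (and optionally smoker->ex)
    misreporting.  Byte-identical output for identical params and seed.
    """
    registry = registry or default_registry()
    pools = _code_pools(registry)
    id_width = max(4, len(str(params.n_patients - 1)))

    events: list[CodedEvent] = []
    surveys: list[SurveyResponse] = []
    truth: list[TruthRecord] = []

    for i in range(params.n_patients):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(i,))
        )
        pid = f"p{i:0{id_width}d}"
        age_at_survey = int(rng.integers(params.age_range[0], params.age_range[1] + 1))
        birth_year = params.survey_year - age_at_survey
        birth_date = dt.date(birth_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        sex = "F" if rng.random() < 0.5 else "M"

        n_years = params.records_end_year - birth_year + 1
        yearly = _life_course(params, rng, n_years)
        record = TruthRecord(pid, birth_date, sex, yearly)
        truth.append(record)

        first_year = max(params.records_start_year, birth_year + 16)
        for year in range(first_year, params.records_end_year + 1):
            for _ in range(int(rng.poisson(params.visit_rate))):
                visit_date = _random_date_in_year(rng, year)
                if rng.random() >= params.record_prob:
                    continue
                state = record.true_status_at(visit_date)
                if state is Category.NEVER:
                    code, value = pools["never"][int(rng.integers(len(pools["never"])))], None
                elif state is Category.EX:
                    code, value = pools["ex"][int(rng.integers(len(pools["ex"])))], None
                else:
                    if pools["smoker_therapy"] and rng.random() < params.therapy_code_prob:
                        pool = pools["smoker_therapy"]
                        code, value = pool[int(rng.integers(len(pool)))], None
                    elif pools["parent"] and rng.random() < 0.2:
                        code = pools["parent"][int(rng.integers(len(pools["parent"])))]
                        value = float(rng.integers(1, 41))
                    else:
                        pool = pools["smoker_status"]
                        code, value = pool[int(rng.integers(len(pool)))], None
                events.append(CodedEvent(pid, visit_date, code, value))

        survey_date = _random_date_in_year(rng, params.survey_year)
        true_state = record.true_status_at(survey_date)
        reported = _TRUTH_TO_COLLAPSED[true_state]
        if reported is CollapsedStatus.EX_SMOKER and rng.random() < params.never_misreport_prob:
            reported = CollapsedStatus.NEVER_SMOKER
        elif reported is CollapsedStatus.SMOKER and rng.random() < params.smoker_misreport_prob:
            reported = CollapsedStatus.EX_SMOKER
        items = _STATUS_TO_ITEMS[reported]
        item = int(items[int(rng.integers(2))]) if items[0] != items[1] else items[0]
        surveys.append(SurveyResponse(pid, survey_date, item=item))

    events.sort(key=lambda e: (e.patient_id, e.event_date, e.code))
    return SyntheticCohort(params=params, events=events, surveys=surveys, truth=truth)


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write events.csv, surveys.csv, truth.csv and demographics.csv."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ev = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in cohort.events],
            "event_date": [e.event_date.isoformat() for e in cohort.events],
            "code": [e.code for e in cohort.events],
            "value": [
                "" if e.value is None else format(e.value, "g") for e in cohort.events
            ],
        }
    )
    paths["events"] = out / "events.csv"
    ev.to_csv(paths["events"], index=False)

    sv = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in cohort.surveys],
            "survey_date": [s.survey_date.isoformat() for s in cohort.surveys],
            "item": [s.item if s.item is not None else "" for s in cohort.surveys],
            "status": [s.status.value for s in cohort.surveys],
        }
    )
    paths["surveys"] = out / "surveys.csv"
    sv.to_csv(paths["surveys"], index=False)

    rows = []
    for t in cohort.truth:
        for age, state in enumerate(t.yearly):
            rows.append(
                {"patient_id": t.patient_id, "year": t.birth_date.year + age, "state": state.value}
            )
    paths["truth"] = out / "truth.csv"
    pd.DataFrame(rows).to_csv(paths["truth"], index=False)

    demo = pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in cohort.truth],
            "birth_date": [t.birth_date.isoformat() for t in cohort.truth],
            "sex": [t.sex for t in cohort.truth],
        }
    )
    paths["demographics"] = out / "demographics.csv"
    demo.to_csv(paths["demographics"], index=False)
    return paths


def dense_recording(params: CohortParams) -> CohortParams:
    """Variant of ``params`` with every visit recorded and frequent visits.

    Used for recovery checks: with faithful, dense coding and no survey
    misreporting the pipeline should reproduce the generator's truth.
    """
    return replace(
        params, visit_rate=12.0, record_prob=1.0, never_misreport_prob=0.0
    )


# Published contingency tables live in smoketrace.reference; re-exported
# here because they serve the same no-real-data purpose as the generator.
from smoketrace.reference import reference_tables  # noqa: E402

__all__.append("reference_tables")
__all__.append("dense_recording")
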