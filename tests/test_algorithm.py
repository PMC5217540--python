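import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smoketrace.algorithm import (
    CollapsedStatus,
    SmokingStatus,
    classify_full,
    classify_nearest,
    classify_no_temporal,
    collapse,
)
from smoketrace.codelist import Category
from smoketrace.timeline import CategorySummary, DatedCategory, summarize_patient

from .conftest import CENSUS_DATES

D = dt.date

EXPECTED_PANEL = {
    "A": SmokingStatus.UNKNOWN_SMOKING_STATUS,
    "B": SmokingStatus.EX_SMOKER,
    "C": SmokingStatus.RELAPSED_SMOKER,
    "D": SmokingStatus.SMOKER,
    "E": SmokingStatus.SMOKER,
    "F": SmokingStatus.EX_SMOKER,
    "G": SmokingStatus.EX_SMOKER,
}


def oracle_classify(dated, census, temporal_check=True):
    """Literal enumeration of the census-scenario rules, from raw events.

    Independent of CategorySummary: spans are recomputed here with plain
    min/max scans and each rule is spelled out in order.
    """
    if not dated:
        return SmokingStatus.NO_INFORMATION
    if all(d.date > census for d in dated):
        if {d.category for d in dated} == {Category.SMOKER}:
            return SmokingStatus.LIKELY_SMOKER
        return SmokingStatus.UNKNOWN_SMOKING_STATUS
    span = {}
    for cat in Category:
        dates = [d.date for d in dated if d.category is cat]
        if dates:
            span[cat] = (min(dates), max(dates))
    has_history = any(
        span[c][0] <= census for c in (Category.EX, Category.SMOKER) if c in span
    )
    containing = {c for c, (lo, hi) in span.items() if lo <= census <= hi}
    if Category.SMOKER in containing and (
        Category.EX in containing or Category.NEVER in containing
    ):
        return SmokingStatus.RELAPSED_SMOKER
    if Category.SMOKER in containing:
        return SmokingStatus.SMOKER
    if Category.EX in containing:
        return SmokingStatus.EX_SMOKER
    if Category.NEVER in containing:
        if temporal_check and has_history:
            return SmokingStatus.EX_SMOKER
        return SmokingStatus.NEVER_SMOKER
    priority = {Category.SMOKER: 0, Category.EX: 1, Category.NEVER: 2}
    boundaries = [(d, c) for c, pair in span.items() for d in pair]
    _, nearest = min(
        ((abs((d - census).days), 0 if d <= census else 1, priority[c]), c)
        for d, c in boundaries
    )
    if nearest is Category.NEVER and temporal_check and has_history:
        return SmokingStatus.EX_SMOKER
    return {
        Category.NEVER: SmokingStatus.NEVER_SMOKER,
        Category.EX: SmokingStatus.EX_SMOKER,
        Category.SMOKER: SmokingStatus.SMOKER,
    }[nearest]


def summary_from(dated):
    by_cat = {}
    for d in dated:
        by_cat.setdefault(d.category, []).append(d.date)
    kw = {}
    for cat, key in [(Category.NEVER, "never"), (Category.EX, "ex"), (Category.SMOKER, "smok")]:
        dates = by_cat.get(cat)
        kw[f"first_{key}"] = min(dates) if dates else None
        kw[f"last_{key}"] = max(dates) if dates else None
    return CategorySummary(**kw)


dated_strategy = st.lists(
    st.builds(
        DatedCategory,
        date=st.dates(min_value=D(1990, 1, 1), max_value=D(2020, 12, 31)),
        category=st.sampled_from(list(Category)),
    ),
    max_size=10,
)
census_strategy = st.dates(min_value=D(1989, 1, 1), max_value=D(2022, 12, 31))


class TestScenarioPanel:
    @pytest.mark.parametrize("label", list(CENSUS_DATES))
    def test_census_walkthrough(self, registry, life_course_events, label):
        summary = summarize_patient(life_course_events, registry)
        assert classify_full(summary, CENSUS_DATES[label]) is EXPECTED_PANEL[label]

    def test_no_temporal_lets_never_designation_stand(self, registry, life_course_events):
        summary = summarize_patient(life_course_events, registry)
        assert classify_no_temporal(summary, CENSUS_DATES["F"]) is SmokingStatus.NEVER_SMOKER
        assert classify_no_temporal(summary, CENSUS_DATES["G"]) is SmokingStatus.NEVER_SMOKER
        for label in "ABCDE":
            assert classify_no_temporal(summary, CENSUS_DATES[label]) is EXPECTED_PANEL[label]


class TestClassifyFull:
    def test_empty_record_is_no_information_at_any_date(self):
        empty = CategorySummary()
        for year in (1990, 2005, 2020):
            assert classify_full(empty, D(year, 6, 1)) is SmokingStatus.NO_INFORMATION

    def test_only_future_smoker_codes_is_likely_smoker(self):
        s = CategorySummary(first_smok=D(2010, 1, 1), last_smok=D(2012, 1, 1))
        assert classify_full(s, D(2005, 1, 1)) is SmokingStatus.LIKELY_SMOKER

    def test_mixed_future_codes_is_unknown(self):
        s = CategorySummary(
            first_smok=D(2010, 1, 1),
            last_smok=D(2012, 1, 1),
            first_ex=D(2011, 1, 1),
            last_ex=D(2013, 1, 1),
        )
        assert classify_full(s, D(2005, 1, 1)) is SmokingStatus.UNKNOWN_SMOKING_STATUS

    def test_never_span_with_prior_smoking_overridden_to_ex(self):
        s = CategorySummary(
            first_never=D(2010, 1, 1),
            last_never=D(2015, 1, 1),
            first_ex=D(2005, 1, 1),
            last_ex=D(2006, 1, 1),
        )
        assert classify_full(s, D(2012, 1, 1)) is SmokingStatus.EX_SMOKER
        assert classify_no_temporal(s, D(2012, 1, 1)) is SmokingStatus.NEVER_SMOKER

    def test_pure_never_record_is_never(self):
        s = CategorySummary(first_never=D(2000, 1, 1), last_never=D(2010, 1, 1))
        assert classify_full(s, D(2005, 1, 1)) is SmokingStatus.NEVER_SMOKER


class TestClassifyNearest:
    def test_empty_is_missing(self):
        assert classify_nearest([], D(2010, 1, 1)) is CollapsedStatus.MISSING

    def test_single_code_at_any_distance(self):
        events = [DatedCategory(D(1995, 1, 1), Category.NEVER)]
        assert classify_nearest(events, D(2015, 1, 1)) is CollapsedStatus.NEVER_SMOKER

    def test_nearer_date_wins(self):
        census = D(2010, 1, 15)
        events = [
            DatedCategory(D(2010, 1, 5), Category.SMOKER),   # 10 days before
            DatedCategory(D(2010, 2, 14), Category.EX),      # 30 days after
        ]
        assert classify_nearest(events, census) is CollapsedStatus.SMOKER

    def test_equidistant_tie_prefers_on_or_before(self):
        census = D(2010, 1, 15)
        events = [
            DatedCategory(D(2010, 1, 5), Category.EX),      # 10 days before
            DatedCategory(D(2010, 1, 25), Category.SMOKER),  # 10 days after
        ]
        assert classify_nearest(events, census) is CollapsedStatus.EX_SMOKER

    def test_same_day_tie_prefers_smoker(self):
        census = D(2010, 1, 15)
        events = [
            DatedCategory(D(2010, 1, 10), Category.NEVER),
            DatedCategory(D(2010, 1, 10), Category.SMOKER),
        ]
        assert classify_nearest(events, census) is CollapsedStatus.SMOKER


class TestCollapse:
    @pytest.mark.parametrize(
        "status,expected",
        [
            (SmokingStatus.NO_INFORMATION, CollapsedStatus.MISSING),
            (SmokingStatus.UNKNOWN_SMOKING_STATUS, CollapsedStatus.MISSING),
            (SmokingStatus.SMOKER, CollapsedStatus.SMOKER),
            (SmokingStatus.RELAPSED_SMOKER, CollapsedStatus.SMOKER),
            (SmokingStatus.LIKELY_SMOKER, CollapsedStatus.SMOKER),
            (SmokingStatus.EX_SMOKER, CollapsedStatus.EX_SMOKER),
            (SmokingStatus.NEVER_SMOKER, CollapsedStatus.NEVER_SMOKER),
        ],
    )
    def test_total_mapping(self, status, expected):
        assert collapse(status) is expected


@settings(max_examples=400, derandomize=True)
@given(dated=dated_strategy, census=census_strategy)
def test_full_classifier_matches_rule_enumeration_oracle(dated, census):
    summary = summary_from(dated)
    assert classify_full(summary, census) is oracle_classify(dated, census)
    assert classify_no_temporal(summary, census) is oracle_classify(
        dated, census, temporal_check=False
    )


@settings(max_examples=400, derandomize=True)
@given(dated=dated_strategy, census=census_strategy)
def test_no_never_after_smoking_evidence(dated, census):
    """Conflict monotonicity: any earlier ex/smoker evidence rules out NEVER."""
    summary = summary_from(dated)
    smoking_firsts = [
        summary.span(c)[0]
        for c in (Category.EX, Category.SMOKER)
        if summary.span(c)[0] is not None
    ]
    result = classify_full(summary, census)
    if smoking_firsts and census >= min(smoking_firsts):
        assert result is not SmokingStatus.NEVER_SMOKER


@settings(max_examples=400, derandomize=True)
@given(dated=dated_strategy, census=census_strategy)
def test_variants_differ_only_where_no_temporal_says_never(dated, census):
    summary = summary_from(dated)
    full = classify_full(summary, census)
    loose = classify_no_temporal(summary, census)
    if full is not loose:
        assert loose is SmokingStatus.NEVER_SMOKER
        assert full is SmokingStatus.EX_SMOKER
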