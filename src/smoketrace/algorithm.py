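"""Smoking-status classification at a census date.

Three classifiers over a patient's longitudinal record:

* :func:`classify_full` — the full life-course algorithm.  It resolves
  temporal conflicts (a never-smoker code recorded after evidence of
  smoking is downgraded to ex-smoker), detects relapse (smoker and
  ex/never evidence spans both containing the census date), and flags
  records with no usable information at the census date.
* :func:`classify_no_temporal` — the same algorithm with the
  previous-smoking override disabled: a never-smoker designation stands
  even when earlier ex/smoker evidence exists.  Relapse detection is
  retained.
* :func:`classify_nearest` — ignores the life course entirely and takes
  the status code nearest in time to the census date (status codes only,
  no therapy or administration evidence).

The seven-level status collapses to the four-level scale
(missing / smoker / ex / never) used for survey comparison and
prevalence: relapse and likely-smoker classes count as smokers, and the
two no-usable-data classes count as missing.
"""

from __future__ import annotations

import datetime as dt
import enum
from typing import Iterable, Optional

from smoketrace.codelist import Category
from smoketrace.timeline import CategorySummary, DatedCategory

__all__ = [
    "SmokingStatus",
    "CollapsedStatus",
    "classify_full",
    "classify_no_temporal",
    "classify_nearest",
    "collapse",
]


class SmokingStatus(enum.Enum):
    """Seven-level classification at a census date."""

    NO_INFORMATION = "NO_INFORMATION"
    UNKNOWN_SMOKING_STATUS = "UNKNOWN_SMOKING_STATUS"
    NEVER_SMOKER = "NEVER_SMOKER"
    EX_SMOKER = "EX_SMOKER"
    RELAPSED_SMOKER = "RELAPSED_SMOKER"
    LIKELY_SMOKER = "LIKELY_SMOKER"
    SMOKER = "SMOKER"


class CollapsedStatus(enum.Enum):
    """Four-level scale used for survey comparison and prevalence."""

    MISSING = "missing"
    SMOKER = "smoker"
    EX_SMOKER = "ex_smoker"
    NEVER_SMOKER = "never_smoker"


# Tie-break priority when two categories are equidistant from the census:
# conservative toward smoking (therapy evidence is treated as smoking).
_CATEGORY_PRIORITY = {Category.SMOKER: 0, Category.EX: 1, Category.NEVER: 2}

_CATEGORY_TO_STATUS = {
    Category.NEVER: SmokingStatus.NEVER_SMOKER,
    Category.EX: SmokingStatus.EX_SMOKER,
    Category.SMOKER: SmokingStatus.SMOKER,
}

_CATEGORY_TO_COLLAPSED = {
    Category.NEVER: CollapsedStatus.NEVER_SMOKER,
    Category.EX: CollapsedStatus.EX_SMOKER,
    Category.SMOKER: CollapsedStatus.SMOKER,
}


def _on_or_before(date: dt.date, census: dt.date) -> bool:
    # A code recorded on the census day reflects status on that day.  The
    # strict "before" reading is a one-character change here.
    return date <= census


def _smoking_evidence_by(summary: CategorySummary, census: dt.date) -> bool:
    """Any EX or SMOKER evidence on or before the census date."""
    for cat in (Category.EX, Category.SMOKER):
        first, _ = summary.span(cat)
        if first is not None and _on_or_before(first, census):
            return True
    return False


def _nearest_category(summary: CategorySummary, census: dt.date) -> Category:
    """Category of the boundary date (any FIRST/LAST) nearest to census.

    Ties prefer the boundary on/before census, then SMOKER > EX > NEVER.
    """
    best = None
    for cat in summary.categories():
        for date in summary.span(cat):
            key = (
                abs((date - census).days),
                0 if _on_or_before(date, census) else 1,
                _CATEGORY_PRIORITY[cat],
            )
            if best is None or key < best[0]:
                best = (key, cat)
    assert best is not None, "caller guarantees a non-empty summary"
    return best[1]


def _classify(summary: CategorySummary, census: dt.date, temporal_check: bool) -> SmokingStatus:
    if summary.is_empty:
        return SmokingStatus.NO_INFORMATION

    present = summary.categories()
    firsts = [summary.span(c)[0] for c in present]
    if not any(_on_or_before(first, census) for first in firsts):
        # Record exists but nothing recorded by the census date.
        if present == [Category.SMOKER]:
            # Smoking starts young; recording often lags initiation by years.
            return SmokingStatus.LIKELY_SMOKER
        return SmokingStatus.UNKNOWN_SMOKING_STATUS

    contains = {c: summary.contains(c, census) for c in Category}
    if contains[Category.SMOKER] and (contains[Category.EX] or contains[Category.NEVER]):
        return SmokingStatus.RELAPSED_SMOKER
    if contains[Category.SMOKER]:
        return SmokingStatus.SMOKER
    if contains[Category.EX]:
        return SmokingStatus.EX_SMOKER
    if contains[Category.NEVER]:
        if temporal_check and _smoking_evidence_by(summary, census):
            return SmokingStatus.EX_SMOKER
        return SmokingStatus.NEVER_SMOKER

    nearest = _nearest_category(summary, census)
    if (
        nearest is Category.NEVER
        and temporal_check
        and _smoking_evidence_by(summary, census)
    ):
        return SmokingStatus.EX_SMOKER
    return _CATEGORY_TO_STATUS[nearest]


def classify_full(summary: CategorySummary, census: dt.date) -> SmokingStatus:
    """Classify smoking status at ``census`` under the full algorithm.

    Evaluation order:

    1. Empty summary -> NO_INFORMATION.
    2. No evidence on/before census -> LIKELY_SMOKER if the record holds
       only smoker-category evidence, else UNKNOWN_SMOKING_STATUS.
    3. Evidence spans containing census: smoker span overlapping an
       ex/never span -> RELAPSED_SMOKER; else smoker -> SMOKER; else ex ->
       EX_SMOKER; else never -> EX_SMOKER when any earlier ex/smoker
       evidence exists (the temporal-conflict override), otherwise
       NEVER_SMOKER.
    4. No span contains census: take the category of the nearest
       first/last boundary date; a provisional NEVER with earlier
       ex/smoker evidence is overridden to EX_SMOKER.

    Total: every summary/census pair yields exactly one status.
    """
    return _classify(summary, census, temporal_check=True)


def classify_no_temporal(summary: CategorySummary, census: dt.date) -> SmokingStatus:
    """The full algorithm without checking for previous smoking status.

    Identical to :func:`classify_full` except a never-smoker designation
    stands regardless of earlier ex/smoker evidence.  Relapse detection
    (overlapping evidence spans) is unchanged.
    """
    return _classify(summary, census, temporal_check=False)


def classify_nearest(
    status_events: Iterable[DatedCategory], census: dt.date
) -> CollapsedStatus:
    """Status of the code dated nearest to census (status codes only).

    ``status_events`` should come from
    :func:`~smoketrace.timeline.informative_events` with ``status_only``
    set.  Empty input -> MISSING.  Ties prefer the event on/before census,
    then SMOKER > EX > NEVER.
    """
    best: Optional[tuple[tuple[int, int, int], Category]] = None
    for ev in status_events:
        key = (
            abs((ev.date - census).days),
            0 if _on_or_before(ev.date, census) else 1,
            _CATEGORY_PRIORITY[ev.category],
        )
        if best is None or key < best[0]:
            best = (key, ev.category)
    if best is None:
        return CollapsedStatus.MISSING
    return _CATEGORY_TO_COLLAPSED[best[1]]


_COLLAPSE = {
    SmokingStatus.NO_INFORMATION: CollapsedStatus.MISSING,
    SmokingStatus.UNKNOWN_SMOKING_STATUS: CollapsedStatus.MISSING,
    SmokingStatus.NEVER_SMOKER: CollapsedStatus.NEVER_SMOKER,
    SmokingStatus.EX_SMOKER: CollapsedStatus.EX_SMOKER,
    SmokingStatus.RELAPSED_SMOKER: CollapsedStatus.SMOKER,
    SmokingStatus.LIKELY_SMOKER: CollapsedStatus.SMOKER,
    SmokingStatus.SMOKER: CollapsedStatus.SMOKER,
}


def collapse(status: SmokingStatus) -> CollapsedStatus:
    """Collapse the seven-level status to the four-level comparison scale."""
    return _COLLAPSE[status]
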