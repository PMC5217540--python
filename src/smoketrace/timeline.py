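"""Reduce a patient's coded events to per-category first/last dates.

The classification algorithm needs only six dates per patient: the first
and last recorded date of a code in each of the three base categories
(FIRST/LAST of NEVER, EX, SMOKER).  The interval [first, last] is that
category's evidence span.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

from smoketrace.codelist import Category, CodeRegistry, NON_STATUS_KINDS, classify_code

__all__ = [
    "CodedEvent",
    "DatedCategory",
    "CategorySummary",
    "informative_events",
    "summarize_patient",
]


@dataclass(frozen=True)
class CodedEvent:
    """One coded row of a patient's GP record (day resolution)."""

    patient_id: str
    event_date: dt.date
    code: str
    value: Optional[float] = None


@dataclass(frozen=True)
class DatedCategory:
    """An informative event reduced to its date and base category."""

    date: dt.date
    category: Category


@dataclass(frozen=True)
class CategorySummary:
    """First/last evidence dates per base category for one patient.

    For each category either both dates are present (first <= last) or
    both are absent; all six absent means the record holds no informative
    smoking events.
    """

    first_never: Optional[dt.date] = None
    last_never: Optional[dt.date] = None
    first_ex: Optional[dt.date] = None
    last_ex: Optional[dt.date] = None
    first_smok: Optional[dt.date] = None
    last_smok: Optional[dt.date] = None

    def __post_init__(self) -> None:
        for cat in Category:
            first, last = self.span(cat)
            if (first is None) != (last is None):
                raise ValueError(f"{cat.value}: first/last must be both set or both absent")
            if first is not None and first > last:
                raise ValueError(f"{cat.value}: first date after last date")

    def span(self, category: Category) -> tuple[Optional[dt.date], Optional[dt.date]]:
        key = {Category.NEVER: "never", Category.EX: "ex", Category.SMOKER: "smok"}[category]
        return getattr(self, f"first_{key}"), getattr(self, f"last_{key}")

    @property
    def is_empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in fields(self))

    def categories(self) -> list[Category]:
        """Categories with any evidence, in fixed NEVER/EX/SMOKER order."""
        return [c for c in Category if self.span(c)[0] is not None]

    def contains(self, category: Category, census: dt.date) -> bool:
        """True iff the category's evidence span contains the census date."""
        first, last = self.span(category)
        return first is not None and first <= census <= last

    def merge(self, other: "CategorySummary") -> "CategorySummary":
        """Per-category min/max merge; equals summarizing concatenated events."""
        kw = {}
        for cat in Category:
            key = {Category.NEVER: "never", Category.EX: "ex", Category.SMOKER: "smok"}[cat]
            firsts = [d for d in (self.span(cat)[0], other.span(cat)[0]) if d is not None]
            lasts = [d for d in (self.span(cat)[1], other.span(cat)[1]) if d is not None]
            kw[f"first_{key}"] = min(firsts) if firsts else None
            kw[f"last_{key}"] = max(lasts) if lasts else None
        return CategorySummary(**kw)


def informative_events(
    events: Iterable[CodedEvent],
    registry: CodeRegistry,
    status_only: bool = False,
) -> list[DatedCategory]:
    """Reduce events to (date, category) pairs, dropping uninformative codes.

    With ``status_only`` set, therapy / cessation-administration / advice
    codes are excluded before reduction — the "GP status codes only"
    comparison variant.
    """
    out: list[DatedCategory] = []
    for ev in events:
        entry = registry.get(ev.code)
        if entry is not None and status_only and entry.kind in NON_STATUS_KINDS:
            continue
        category = classify_code(registry, ev.code, ev.value)
        if category is not None:
            out.append(DatedCategory(ev.event_date, category))
    return out


def summarize_patient(
    events: Sequence[CodedEvent], registry: CodeRegistry
) -> CategorySummary:
    """Build the FIRST/LAST category summary for one patient's events.

    Uninformative codes contribute nothing; the result is independent of
    input order.  Events must all belong to the same patient.
    """
    ids = {ev.patient_id for ev in events}
    if len(ids) > 1:
        raise ValueError(f"events span multiple patients: {sorted(ids)}")
    kw: dict[str, Optional[dt.date]] = {}
    dated = informative_events(events, registry)
    for cat in Category:
        key = {Category.NEVER: "never", Category.EX: "ex", Category.SMOKER: "smok"}[cat]
        dates = [dc.date for dc in dated if dc.category is cat]
        kw[f"first_{key}"] = min(dates) if dates else None
        kw[f"last_{key}"] = max(dates) if dates else None
    return CategorySummary(**kw)
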