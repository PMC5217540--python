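"""Clinical-code registry: smoking categories, sub-groups and intensity.

UK primary-care records code smoking with a family of Read V2 codes: direct
status codes (never / ex / current smoker), consumption-intensity codes,
nicotine-replacement and other cessation-therapy prescriptions,
cessation-administration and advice codes, and the hierarchy parent code
("Tobacco consumption") which on its own carries no status information but
is often recorded with a cigarettes-per-day value.  This module maps codes
to their base category and resolves the parent-code and zero-value rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

__all__ = [
    "Category",
    "CodeKind",
    "IntensityClass",
    "CodeEntry",
    "CodeRegistry",
    "load_codelist",
    "write_codelist",
    "default_registry",
    "classify_code",
    "classify_intensity",
]


class Category(enum.Enum):
    """Base smoking category a clinical code provides evidence for."""

    NEVER = "NEVER"
    EX = "EX"
    SMOKER = "SMOKER"


class CodeKind(enum.Enum):
    """What sort of code this is.

    ``status`` and ``intensity`` codes state a smoking status directly;
    ``therapy``, ``cessation_admin`` and ``advice`` codes imply one
    (a patient prescribed nicotine replacement is treated as a current
    smoker unless later coded otherwise); ``parent`` is the hierarchy
    head whose meaning depends on an attached numeric value.
    """

    STATUS = "status"
    INTENSITY = "intensity"
    THERAPY = "therapy"
    CESSATION_ADMIN = "cessation_admin"
    ADVICE = "advice"
    PARENT = "parent"


#: Kinds excluded from the "status codes only" comparison variant.
NON_STATUS_KINDS = frozenset(
    {CodeKind.THERAPY, CodeKind.CESSATION_ADMIN, CodeKind.ADVICE}
)


class IntensityClass(enum.Enum):
    """Smoking intensity, ordered lightest to heaviest."""

    TRIVIAL = "trivial"
    LIGHT = "light"
    MEDIUM = "medium"
    HEAVY = "heavy"
    VERY_HEAVY = "very_heavy"

    @property
    def rank(self) -> int:
        return _INTENSITY_ORDER.index(self)


_INTENSITY_ORDER = [
    IntensityClass.TRIVIAL,
    IntensityClass.LIGHT,
    IntensityClass.MEDIUM,
    IntensityClass.HEAVY,
    IntensityClass.VERY_HEAVY,
]


@dataclass(frozen=True)
class CodeEntry:
    """One clinical code and its classification.

    ``base_category`` is ``None`` only for the parent code, whose category
    depends on the recorded value (see :func:`classify_code`).
    """

    code: str
    base_category: Optional[Category]
    subgroup: str
    kind: CodeKind
    intensity_class: Optional[IntensityClass] = None

    def __post_init__(self) -> None:
        if self.kind is CodeKind.PARENT:
            if self.base_category is not None:
                raise ValueError(
                    f"parent code {self.code!r} must not carry a fixed category"
                )
        elif self.base_category is None:
            raise ValueError(f"code {self.code!r} has no base category")
        if self.kind in (CodeKind.THERAPY, CodeKind.CESSATION_ADMIN):
            if self.base_category is Category.NEVER:
                raise ValueError(
                    f"{self.kind.value} code {self.code!r} cannot be NEVER: "
                    "therapy/administration codes imply smoking history"
                )


class CodeRegistry:
    """Immutable lookup from clinical code to :class:`CodeEntry`.

    Unknown codes are a distinguishable outcome (``get`` returns ``None``),
    not an error: real extracts contain plenty of non-smoking codes.
    """

    def __init__(self, entries: Iterable[CodeEntry]):
        self._entries: dict[str, CodeEntry] = {}
        for entry in entries:
            if entry.code in self._entries:
                raise ValueError(f"duplicate code in codelist: {entry.code!r}")
            self._entries[entry.code] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, code: str) -> Optional[CodeEntry]:
        return self._entries.get(code)

    @property
    def entries(self) -> Mapping[str, CodeEntry]:
        return dict(self._entries)

    def status_only(self) -> "CodeRegistry":
        """Subset excluding therapy, cessation-administration and advice codes."""
        return CodeRegistry(
            e for e in self._entries.values() if e.kind not in NON_STATUS_KINDS
        )

    def codes(
        self,
        category: Optional[Category] = None,
        kind: Optional[CodeKind] = None,
    ) -> list[str]:
        """Codes filtered by category and/or kind, in registry order."""
        out = []
        for e in self._entries.values():
            if category is not None and e.base_category is not category:
                continue
            if kind is not None and e.kind is not kind:
                continue
            out.append(e.code)
        return out


_COLUMNS = ["code", "base_category", "subgroup", "kind", "intensity_class"]


def load_codelist(path: Union[str, Path]) -> CodeRegistry:
    """Load a codelist CSV into a :class:`CodeRegistry`.

    Required columns: ``code,base_category,subgroup,kind``; optional
    ``intensity_class``.  ``base_category`` is blank for the parent code.
    Duplicate codes are rejected with the offending code named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"codelist {path} missing required columns: {missing}")
    entries = []
    for row in df.itertuples(index=False):
        cat = getattr(row, "base_category", "")
        intensity = getattr(row, "intensity_class", "")
        entries.append(
            CodeEntry(
                code=row.code,
                base_category=Category(cat) if cat else None,
                subgroup=row.subgroup,
                kind=CodeKind(row.kind),
                intensity_class=IntensityClass(intensity) if intensity else None,
            )
        )
    return CodeRegistry(entries)


def write_codelist(registry: CodeRegistry, path: Union[str, Path]) -> None:
    """Write a registry back to the codelist CSV format (load round-trips)."""
    rows = [
        {
            "code": e.code,
            "base_category": e.base_category.value if e.base_category else "",
            "subgroup": e.subgroup,
            "kind": e.kind.value,
            "intensity_class": e.intensity_class.value if e.intensity_class else "",
        }
        for e in registry
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def default_registry() -> CodeRegistry:
    """The packaged default codelist.

    A synthetic representative stand-in: the real research codelist is not
    publicly distributable, so this registry mirrors the published group /
    sub-group structure (two never-smoker codes, ex-smoker sub-groups,
    NRT/therapy/administration/advice/intensity groups under SMOKER) with
    illustrative Read-V2-style codes.  Large sub-groups (91 distinct NRT
    product codes in the original) are collapsed to a few representative
    entries.  Substitute a real codelist via :func:`load_codelist` for use
    on actual extracts.
    """
    ref = resources.files("smoketrace.data") / "codelist_synthetic_default.csv"
    with resources.as_file(ref) as path:
        return load_codelist(path)


def classify_code(
    registry: CodeRegistry, code: str, value: Optional[float] = None
) -> Optional[Category]:
    """Resolve one recorded code (with optional numeric value) to a category.

    Returns ``None`` when the code is uninformative: unknown codes, and the
    parent code without a positive value.  A parent code recorded with a
    positive cigarettes-per-day value counts as SMOKER evidence; a zero may
    mean either a non-smoker or a smoker depending on the recording GP, so
    it contributes nothing.
    """
    if value is not None and value < 0:
        raise ValueError(f"negative recorded value {value!r} for code {code!r}")
    entry = registry.get(code)
    if entry is None:
        return None
    if entry.kind is CodeKind.PARENT:
        if value is not None and value > 0:
            return Category.SMOKER
        return None
    return entry.base_category


def classify_intensity(
    cigs_per_day: Optional[float] = None,
    minutes_to_first: Optional[float] = None,
) -> Optional[IntensityClass]:
    """Classify smoking intensity from consumption and/or time to first cigarette.

    Consumption bands are half-open, the highest applicable class winning:
    [1, 10) light, [10, 20) medium, [20, 40) heavy, >= 40 very heavy.
    Time to first cigarette on waking: > 60 min light, (30, 60] medium,
    (5, 30] heavy, <= 5 very heavy.  When both measures are supplied the
    heavier class is returned.  A consumption of zero is uninformative
    (``None``): a zero count may be a non-smoker or a smoker.  Trivial
    smoking has no numeric band and is assignable only via explicit codes.
    """
    if cigs_per_day is None and minutes_to_first is None:
        raise ValueError("supply cigs_per_day and/or minutes_to_first")
    classes: list[IntensityClass] = []
    if cigs_per_day is not None:
        if cigs_per_day < 0:
            raise ValueError("cigs_per_day must be nonnegative")
        if cigs_per_day >= 40:
            classes.append(IntensityClass.VERY_HEAVY)
        elif cigs_per_day >= 20:
            classes.append(IntensityClass.HEAVY)
        elif cigs_per_day >= 10:
            classes.append(IntensityClass.MEDIUM)
        elif cigs_per_day >= 1:
            classes.append(IntensityClass.LIGHT)
        # 0 <= cigs_per_day < 1: uninformative, contributes no class
    if minutes_to_first is not None:
        if minutes_to_first < 0:
            raise ValueError("minutes_to_first must be nonnegative")
        if minutes_to_first <= 5:
            classes.append(IntensityClass.VERY_HEAVY)
        elif minutes_to_first <= 30:
            classes.append(IntensityClass.HEAVY)
        elif minutes_to_first <= 60:
            classes.append(IntensityClass.MEDIUM)
        else:
            classes.append(IntensityClass.LIGHT)
    if not classes:
        return None
    return max(classes, key=lambda c: c.rank)
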