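"""GP-vs-survey agreement: contingency tables, Cohen's kappa, discordance.

The survey instrument asks a five-item smoking question; items 1–2 map to
smoker, 3–4 to ex-smoker, 5 to never smoker.  GP-derived collapsed
statuses are cross-tabulated against survey self-report in a 4x4 table
whose first row/column hold missing data.  Kappa is computed on the
complete pairs only (missing row and column dropped), either on the 3x3
smoker/ex/never grid (three-status solution) or after amalgamating ex and
never smokers into a single non-smoker category on both axes (two-status
solution).
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from smoketrace.algorithm import CollapsedStatus

__all__ = [
    "STATUS_ORDER",
    "SurveyResponse",
    "AgreementTable",
    "KappaResult",
    "AltmanBand",
    "build_agreement_table",
    "complete_pairs",
    "collapse_two_status",
    "cohen_kappa",
    "altman_band",
    "discordance_summary",
    "Proportion",
]

#: Fixed axis order of the 4x4 agreement table.
STATUS_ORDER = [
    CollapsedStatus.MISSING,
    CollapsedStatus.SMOKER,
    CollapsedStatus.EX_SMOKER,
    CollapsedStatus.NEVER_SMOKER,
]

_STATUS_INDEX = {s: i for i, s in enumerate(STATUS_ORDER)}

_ITEM_TO_STATUS = {
    1: CollapsedStatus.SMOKER,
    2: CollapsedStatus.SMOKER,
    3: CollapsedStatus.EX_SMOKER,
    4: CollapsedStatus.EX_SMOKER,
    5: CollapsedStatus.NEVER_SMOKER,
}


@dataclass(frozen=True)
class SurveyResponse:
    """One person's survey self-report.

    Either ``item`` (the 1–5 questionnaire response) or ``status`` must be
    supplied; when ``item`` is present the status is derived from it.
    """

    patient_id: str
    survey_date: dt.date
    item: Optional[int] = None
    status: Optional[CollapsedStatus] = None

    def __post_init__(self) -> None:
        if self.item is not None:
            if self.item not in _ITEM_TO_STATUS:
                raise ValueError(f"survey item must be 1-5, got {self.item}")
            derived = _ITEM_TO_STATUS[self.item]
            if self.status is None:
                object.__setattr__(self, "status", derived)
            elif self.status is not derived:
                raise ValueError(
                    f"item {self.item} implies {derived.value}, got {self.status.value}"
                )
        elif self.status is None:
            object.__setattr__(self, "status", CollapsedStatus.MISSING)


class AgreementTable:
    """4x4 GP-vs-survey contingency table (rows GP, columns survey).

    Axis order is missing / smoker / ex-smoker / never-smoker.
    """

    def __init__(self, counts, suppressed: Optional[set[tuple[int, int]]] = None):
        arr = np.asarray(counts, dtype=np.int64)
        if arr.shape != (4, 4):
            raise ValueError(f"agreement table must be 4x4, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("agreement table counts must be nonnegative")
        self.counts = arr
        #: cells rendered as "<5" under small-count disclosure control;
        #: stored at their marginal-implied values.
        self.suppressed = frozenset(suppressed or ())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def cell(self, gp: CollapsedStatus, survey: CollapsedStatus) -> int:
        return int(self.counts[_STATUS_INDEX[gp], _STATUS_INDEX[survey]])

    def __eq__(self, other) -> bool:
        return isinstance(other, AgreementTable) and np.array_equal(
            self.counts, other.counts
        )

    def to_dataframe(self, suppress_small_counts: bool = False) -> pd.DataFrame:
        """Labelled table; optionally render any cell below 5 as ``"<5"``.

        Suppression affects the rendering only: row/column totals remain the
        true sums, mirroring disclosure-controlled outputs from trusted
        research environments.
        """
        labels = [s.value for s in STATUS_ORDER]
        if suppress_small_counts:
            body = self.counts.astype(object)
            for i in range(4):
                for j in range(4):
                    if body[i, j] < 5 or (i, j) in self.suppressed:
                        body[i, j] = "<5"
        else:
            body = self.counts
        return pd.DataFrame(body, index=labels, columns=labels)


def build_agreement_table(
    gp_statuses: Mapping[str, CollapsedStatus],
    survey: Iterable[SurveyResponse],
) -> AgreementTable:
    """Cross-tabulate GP collapsed status against survey self-report.

    Every surveyed person contributes to exactly one cell; people absent
    from ``gp_statuses`` count as GP-missing.  Duplicate survey entries for
    one person are rejected.
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    seen: set[str] = set()
    for resp in survey:
        if resp.patient_id in seen:
            raise ValueError(f"duplicate survey response for patient {resp.patient_id!r}")
        seen.add(resp.patient_id)
        gp = gp_statuses.get(resp.patient_id, CollapsedStatus.MISSING)
        counts[_STATUS_INDEX[gp], _STATUS_INDEX[resp.status]] += 1
    return AgreementTable(counts)


def complete_pairs(table: AgreementTable) -> np.ndarray:
    """Drop the missing row and column: the 3x3 (smoker, ex, never) grid."""
    return table.counts[1:, 1:].copy()


def collapse_two_status(grid: np.ndarray) -> np.ndarray:
    """Amalgamate ex- and never-smokers into one non-smoker category.

    Takes the 3x3 complete-pairs grid and returns the 2x2
    (smoker, non-smoker) grid; the grand total is preserved.
    """
    g = np.asarray(grid)
    if g.shape != (3, 3):
        raise ValueError(f"expected a 3x3 grid, got {g.shape}")
    return np.array(
        [
            [g[0, 0], g[0, 1:].sum()],
            [g[1:, 0].sum(), g[1:, 1:].sum()],
        ],
        dtype=g.dtype,
    )


class AltmanBand(enum.Enum):
    """Altman's qualitative interpretation bands for kappa."""

    POOR = "poor"
    FAIR = "fair"
    MODERATE = "moderate"
    GOOD = "good"
    VERY_GOOD = "very good"


def altman_band(kappa: float) -> AltmanBand:
    if kappa <= 0.20:
        return AltmanBand.POOR
    if kappa <= 0.40:
        return AltmanBand.FAIR
    if kappa <= 0.60:
        return AltmanBand.MODERATE
    if kappa <= 0.80:
        return AltmanBand.GOOD
    return AltmanBand.VERY_GOOD


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its large-sample 95% confidence interval."""

    kappa: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    po: float
    pe: float

    @property
    def band(self) -> AltmanBand:
        return altman_band(self.kappa)

    def __str__(self) -> str:
        return (
            f"kappa={self.kappa:.2f} (95% CI {self.ci_low:.2f}, {self.ci_high:.2f}), "
            f"n={self.n}, agreement {self.band.value}"
        )


def cohen_kappa(grid: Union[np.ndarray, list]) -> KappaResult:
    """Unweighted Cohen's kappa on a square contingency grid.

    kappa = (Po - Pe) / (1 - Pe) with Po the observed agreement (diagonal
    proportion) and Pe the chance agreement from the marginals.  The
    standard error is the large-sample form
    se = sqrt(Po (1 - Po) / (N (1 - Pe)^2)) and the CI is kappa +/- 1.96 se.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1] or g.shape[0] < 2:
        raise ValueError(f"kappa needs a square grid of side >= 2, got {g.shape}")
    if (g < 0).any():
        raise ValueError("counts must be nonnegative")
    n = g.sum()
    if n <= 0:
        raise ValueError("kappa is undefined on an empty grid")
    po = np.trace(g) / n
    pe = float(g.sum(axis=1) @ g.sum(axis=0)) / n**2
    if pe >= 1.0:
        raise ZeroDivisionError(
            "kappa undefined: chance agreement is 1 (degenerate marginals)"
        )
    kappa = (po - pe) / (1 - pe)
    se = float(np.sqrt(po * (1 - po) / (n * (1 - pe) ** 2)))
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci_low=float(kappa - 1.96 * se),
        ci_high=float(kappa + 1.96 * se),
        n=int(n),
        po=float(po),
        pe=float(pe),
    )


@dataclass(frozen=True)
class Proportion:
    """A named discordance proportion with its numerator and denominator."""

    name: str
    numerator: int
    denominator: int

    @property
    def value(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def percent(self) -> Optional[float]:
        v = self.value
        return None if v is None else 100.0 * v


def discordance_summary(table: AgreementTable) -> dict[str, Proportion]:
    """The headline GP-vs-survey discordance proportions.

    Denominators are full survey column totals (including GP-missing rows),
    except the excess-smoker ratio which compares the GP smoker row total
    with the survey smoker column total.  Zero denominators yield an
    undefined (``None``-valued) proportion rather than an error.
    """
    S, E, N, M = (
        CollapsedStatus.SMOKER,
        CollapsedStatus.EX_SMOKER,
        CollapsedStatus.NEVER_SMOKER,
        CollapsedStatus.MISSING,
    )
    col = {s: int(table.col_totals[_STATUS_INDEX[s]]) for s in STATUS_ORDER}
    row = {s: int(table.row_totals[_STATUS_INDEX[s]]) for s in STATUS_ORDER}
    out = {
        "survey_never_gp_ex": Proportion("survey_never_gp_ex", table.cell(E, N), col[N]),
        "survey_ex_gp_never": Proportion("survey_ex_gp_never", table.cell(N, E), col[E]),
        "survey_ex_gp_smoker": Proportion("survey_ex_gp_smoker", table.cell(S, E), col[E]),
        "gp_excess_smokers": Proportion("gp_excess_smokers", row[S] - col[S], col[S]),
        "missing_gp": Proportion("missing_gp", row[M], table.grand_total),
        "missing_survey": Proportion("missing_survey", col[M], table.grand_total),
    }
    return out
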