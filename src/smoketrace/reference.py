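"""Published GP-vs-survey contingency tables, packaged as reference data.

The original algorithm was evaluated inside a trusted research
environment by linking Welsh GP records, at person level, to the 2013 and
2014 Welsh Health Survey self-reports (6836 linked individuals).  The
patient-level data are protected, but the three published 4x4 contingency
tables — one per classification variant — fully determine the agreement
analysis, so they ship here as in-memory grids.

Two quirks of the published tables are preserved explicitly:

* Disclosure control suppressed the missing/missing cell of each table as
  "<5"; the values stored here are the marginal-implied ones (5 in each
  case), flagged in ``AgreementTable.suppressed``.
* The nearest-status table's printed missing-row total (423) disagrees
  with its own cells and with the column totals, which both imply 432;
  the cell-consistent value is stored (see ``NEAREST_ROW_TOTAL_ERRATUM``).
"""

from __future__ import annotations

from smoketrace.agreement import AgreementTable

__all__ = ["reference_tables", "NEAREST_ROW_TOTAL_ERRATUM"]

#: The nearest-status table prints a missing-row total of 423 where the
#: cells and column totals imply 432; the grid below is cell-consistent.
NEAREST_ROW_TOTAL_ERRATUM = {"printed": 423, "cell_consistent": 432}

_SUPPRESSED = {(0, 0)}  # missing/missing cell, printed "<5", implied value 5

# Rows: GP missing/smoker/ex/never.  Columns: survey missing/smoker/ex/never.
_FULL = [
    [5, 89, 120, 199],
    [17, 1040, 426, 209],
    [34, 130, 1449, 1104],
    [16, 42, 186, 1770],
]

_NO_TEMPORAL = [
    [5, 99, 120, 199],
    [16, 1017, 452, 236],
    [22, 112, 1108, 126],
    [29, 73, 501, 2721],
]

_NEAREST = [
    [5, 100, 124, 203],
    [10, 985, 194, 20],
    [25, 133, 1323, 143],
    [32, 83, 540, 2916],
]


def reference_tables() -> dict[str, AgreementTable]:
    """The three published contingency tables, keyed by variant.

    Keys: ``"full"`` (full life-course algorithm), ``"no_temporal"``
    (temporal checking disabled), ``"nearest"`` (nearest status code).
    Every table has grand total 6836.
    """
    return {
        "full": AgreementTable(_FULL, suppressed=_SUPPRESSED),
        "no_temporal": AgreementTable(_NO_TEMPORAL, suppressed=_SUPPRESSED),
        "nearest": AgreementTable(_NEAREST, suppressed=_SUPPRESSED),
    }
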