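import datetime as dt

import pytest

from smoketrace.codelist import default_registry
from smoketrace.timeline import CodedEvent

D = dt.date


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def life_course_events():
    """One patient whose record walks through every census scenario.

    Evidence spans: EX 1998-03-01..2003-03-01, SMOKER 2001-02-01..2005-02-01
    (overlapping the EX span), NEVER 2008-04-01..2012-04-01 (recorded after
    the smoking history — the temporal conflict the full algorithm exists
    to resolve).
    """
    return [
        CodedEvent("scenario", D(1998, 3, 1), "137F."),   # ex smoker
        CodedEvent("scenario", D(2003, 3, 1), "137S."),   # ex smoker
        CodedEvent("scenario", D(2001, 2, 1), "137R."),   # current smoker
        CodedEvent("scenario", D(2005, 2, 1), "1374."),   # medium smoker
        CodedEvent("scenario", D(2008, 4, 1), "1371."),   # never smoked
        CodedEvent("scenario", D(2012, 4, 1), "137l."),   # never smoked
    ]


#: Census dates A-G walking left to right across the record above.
CENSUS_DATES = {
    "A": D(1997, 1, 1),   # before any evidence
    "B": D(1999, 6, 1),   # inside EX span only
    "C": D(2002, 6, 1),   # inside EX and SMOKER spans
    "D": D(2004, 6, 1),   # inside SMOKER span only
    "E": D(2006, 6, 1),   # in a gap, last smoker date nearest
    "F": D(2009, 6, 1),   # inside NEVER span, smoking history before
    "G": D(2013, 6, 1),   # after all evidence, never dates nearest
}
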