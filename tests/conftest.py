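import calendar
from datetime import date, timedelta

import pytest

from dvconcord.lexicon import default_crosswalk, default_hierarchy, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def crosswalk():
    return default_crosswalk()


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


def shift_months(d: date, k: int) -> date:
    """Independent calendar-month shift with day-of-month clamping."""
    y = d.year + (d.month - 1 + k) // 12
    m = (d.month - 1 + k) % 12 + 1
    day = min(d.day, calendar.monthrange(y, m)[1])
    return date(y, m, day)


def brute_force_in_window(event_date, start, end, months):
    """Day-enumeration oracle for symmetric month windows (closed, overlap)."""
    lo = shift_months(event_date, -months)
    hi = shift_months(event_date, months)
    d = start
    while d <= end:
        if lo <= d <= hi:
            return True
        d += timedelta(days=1)
    return False
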