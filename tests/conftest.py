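import datetime as dt
import math

import pytest

from adtrends.claims import DispensationRecord, StudyCalendar

DAY0 = dt.date(2018, 3, 1)


@pytest.fixture
def calendar() -> StudyCalendar:
    return StudyCalendar()


def make_record(day: int, atc: str = "N06AB06", subject: str = "S1",
                n_packages: int = 1, units: int = 30, strength: float = 50.0,
                sex: str = "F", birth: dt.date = dt.date(1998, 5, 2),
                origin: dt.date = DAY0) -> DispensationRecord:
    """Dispensation at ``origin + day`` with a configurable pack."""
    return DispensationRecord(
        subject_id=subject, sex=sex, birth_date=birth,
        dispensation_date=origin + dt.timedelta(days=day), atc_code=atc,
        drug_name="", n_packages=n_packages, units_per_package=units,
        strength_per_unit=strength)


def day_by_day_episodes(fills: list[tuple[int, float]],
                        grace_factor: float) -> list[tuple[int, int]]:
    """Independent stock-simulation oracle for episode boundaries.

    ``fills`` are (day, days_of_supply) pairs in any order.  The timeline is
    walked one day at a time: supply is restocked on each fill day (same-day
    fills pooled), treatment is considered discontinued once the days since
    the most recent fill exceed ``grace_factor`` times that fill's supply,
    and exposure ends when the last fill's supply runs out (a partial final
    day counts as exposed).  Returns half-open (start, end) day intervals;
    an interval never runs past the start of its successor.
    """
    pooled: dict[int, float] = {}
    for day, supply in fills:
        pooled[day] = pooled.get(day, 0.0) + supply
    t0 = min(pooled)
    horizon = max(pooled) + math.ceil(max(pooled.values()) * (grace_factor + 1)) + 2
    episodes: list[list[int]] = []
    start = None
    last_fill, last_supply = None, 0.0
    for t in range(t0, horizon + 1):
        expired = (start is not None
                   and t - last_fill > grace_factor * last_supply)
        if expired:
            episodes.append([start, last_fill + math.ceil(last_supply)])
            start = None
        if t in pooled:
            if start is None:
                start = t
            last_fill, last_supply = t, pooled[t]
    if start is not None:
        episodes.append([start, last_fill + math.ceil(last_supply)])
    for cur, nxt in zip(episodes, episodes[1:]):
        cur[1] = min(cur[1], nxt[0])
    return [(a, b) for a, b in episodes]
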