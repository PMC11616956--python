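import datetime as dt

import pytest

from gallop.events import EventRecord, HorseRecord, truncate_career
from gallop.simulate import simulate_study


def day(n: int) -> dt.date:
    """Day n of an arbitrary fixed calendar origin."""

    return dt.date(2019, 1, 1) + dt.timedelta(days=n)


def make_horse(horse_id, specs, birth=None, sex="male"):
    """Build a horse from (day, type, distance) triples."""

    events = tuple(
        EventRecord(horse_id, day(d), kind, dist) for d, kind, dist in specs
    )
    return HorseRecord(horse_id=horse_id, sex=sex, birth_date=birth, events=events)


@pytest.fixture
def mixed_career():
    """2 races (6 F, 30 days apart) + 3 works (4 F); career 60 days, no layups."""

    horse = make_horse(
        "h1",
        [
            (0, "race", 6.0),
            (15, "work", 4.0),
            (30, "race", 6.0),
            (45, "work", 4.0),
            (60, "work", 4.0),
        ],
        birth=day(0) - dt.timedelta(days=900),
    )
    return horse, truncate_career(horse, day(60))


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic study shared by matching/pipeline tests."""

    return simulate_study(psg_n=6, nonpsg_n=6, controls_per_case=3, seed=11)
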