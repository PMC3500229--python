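from __future__ import annotations

from datetime import date, timedelta

import pytest

from phenotyper.claims_model import ClaimsDataset, Person, PersonClaims
from phenotyper.codesets import default_registry
from phenotyper.cohort_builder import CohortMember
from phenotyper.config import DEFAULT_CONFIG

BASE = date(2000, 1, 1)


def day(n: int) -> date:
    """Calendar day n of the test timeline (day 0 = 2000-01-01)."""
    return BASE + timedelta(days=n)


def make_person(pid: str = "p1", birth: date = date(1988, 1, 1), sex: str = "F") -> PersonClaims:
    return PersonClaims(person=Person(pid, birth, sex))


def make_member(pid: str = "p1", start: int = 0, end: int = 600) -> CohortMember:
    t0 = day(start) - timedelta(days=1)
    return CohortMember(
        person_id=pid, time_zero=t0, qualifying_fill_date=t0,
        followup_start=day(start), followup_end=day(end),
        censor_reason="study_end",
    )


def dataset_of(*person_claims: PersonClaims) -> ClaimsDataset:
    ds = ClaimsDataset()
    for pc in person_claims:
        ds.persons[pc.person.person_id] = pc
    ds.sort_claims()
    return ds


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG
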