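"""Typed in-memory model of person-level administrative claims, plus readers
and writers for the delimited-text interchange format.

Files (comma-separated, UTF-8, ISO-8601 dates, one header row):

==================  ==========================================================
persons.csv         person_id, birth_date, sex[, death_date]
enrollment.csv      person_id, start_date, end_date
inpatient.csv       person_id, admission_date, discharge_date, primary_dx,
                    secondary_dx, admission_dx   (multi-valued: ";"-joined)
outpatient.csv      person_id, visit_date, primary_dx, secondary_dx, setting
prescriptions.csv   person_id, fill_date, drug_class, drug_name[, days_supplied]
procedures.csv      person_id, service_date, procedure_code
exclusion_flags.csv person_id, flag, start_date, end_date      (optional)
==================  ==========================================================

All dates are whole calendar days and every interval in this package is
closed on both ends.  Rows failing type or invariant checks are collected
into a rejects report rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Person",
    "EnrollmentSpell",
    "InpatientStay",
    "OutpatientVisit",
    "PrescriptionFill",
    "ProcedureClaim",
    "ExclusionFlag",
    "EncounterEvidence",
    "ClaimsDataset",
    "RejectedRow",
    "ClaimsValidationError",
    "read_claims",
    "write_claims",
    "normalize_enrollment",
]

DRUG_CLASSES = ("insulin", "insulin_adjunct", "oral_hypoglycemic", "study_psychotropic", "other")
SETTINGS = ("outpatient", "emergency", "physician_inpatient")
ENCOUNTER_TYPES = ("inpatient_primary", "inpatient_secondary", "outpatient", "prescription")
EXCLUSION_FLAGS = (
    "life_threatening_illness",
    "institutional_residence",
    "schizophrenia_psychosis",
    "pregnancy",
    "pcos",
)


class ClaimsValidationError(ValueError):
    """Raised in strict mode when a dataset contains rejected rows."""


@dataclass(frozen=True, slots=True)
class Person:
    person_id: str
    birth_date: date
    sex: str  # "F" | "M"
    death_date: date | None = None


@dataclass(frozen=True, slots=True)
class EnrollmentSpell:
    person_id: str
    start_date: date
    end_date: date


@dataclass(frozen=True, slots=True)
class InpatientStay:
    person_id: str
    admission_date: date
    discharge_date: date
    primary_dx: str
    secondary_dx: tuple[str, ...] = ()
    admission_dx: tuple[str, ...] = ()


@dataclass(frozen=True, slots=True)
class OutpatientVisit:
    person_id: str
    visit_date: date
    primary_dx: str
    secondary_dx: tuple[str, ...] = ()
    setting: str = "outpatient"


@dataclass(frozen=True, slots=True)
class PrescriptionFill:
    person_id: str
    fill_date: date
    drug_class: str
    drug_name: str = ""
    days_supplied: int | None = None


@dataclass(frozen=True, slots=True)
class ProcedureClaim:
    person_id: str
    service_date: date
    procedure_code: str


@dataclass(frozen=True, slots=True)
class ExclusionFlag:
    person_id: str
    flag: str
    start_date: date
    end_date: date


@dataclass(frozen=True, slots=True)
class EncounterEvidence:
    """One diabetes-related medical care encounter with its initial index date."""

    person_id: str
    encounter_type: str  # one of ENCOUNTER_TYPES
    event_date: date  # t_x, initial
    source_row: str = ""


@dataclass(frozen=True, slots=True)
class RejectedRow:
    table: str
    row_index: int
    reason: str


@dataclass(slots=True)
class PersonClaims:
    """All claims for one person, each list sorted by date."""

    person: Person
    enrollment: list[EnrollmentSpell] = field(default_factory=list)
    inpatient: list[InpatientStay] = field(default_factory=list)
    outpatient: list[OutpatientVisit] = field(default_factory=list)
    prescriptions: list[PrescriptionFill] = field(default_factory=list)
    procedures: list[ProcedureClaim] = field(default_factory=list)
    exclusion_flags: list[ExclusionFlag] = field(default_factory=list)


@dataclass(slots=True)
class ClaimsDataset:
    """A claims dataset keyed by person, with the rejects report from loading."""

    persons: dict[str, PersonClaims] = field(default_factory=dict)
    rejects: list[RejectedRow] = field(default_factory=list)

    def person_ids(self) -> list[str]:
        return list(self.persons)

    def __len__(self) -> int:
        return len(self.persons)

    def get(self, person_id: str) -> PersonClaims:
        return self.persons[person_id]

    def add_person(self, person: Person) -> PersonClaims:
        if person.person_id in self.persons:
            raise ClaimsValidationError(f"duplicate person_id {person.person_id!r}")
        pc = PersonClaims(person=person)
        self.persons[person.person_id] = pc
        return pc

    def sort_claims(self) -> None:
        for pc in self.persons.values():
            pc.enrollment.sort(key=lambda s: (s.start_date, s.end_date))
            pc.inpatient.sort(key=lambda s: (s.admission_date, s.discharge_date))
            pc.outpatient.sort(key=lambda v: v.visit_date)
            pc.prescriptions.sort(key=lambda f: f.fill_date)
            pc.procedures.sort(key=lambda p: p.service_date)
            pc.exclusion_flags.sort(key=lambda f: f.start_date)


# ---------------------------------------------------------------------------
# enrollment normalization

def normalize_enrollment(
    spells: Sequence[EnrollmentSpell], max_gap_days: int = 7
) -> list[EnrollmentSpell]:
    """Merge overlapping/abutting spells and gaps of at most ``max_gap_days``.

    The gap between a spell ending on day e and one starting on day s is
    ``s - e - 1`` days (a spell ending Mar 31 abuts one starting Apr 1).
    Idempotent and order-insensitive; covered person-days never decrease.
    """
    if not spells:
        return []
    pid = spells[0].person_id
    ordered = sorted(spells, key=lambda s: (s.start_date, s.end_date))
    out: list[EnrollmentSpell] = []
    cur_start, cur_end = ordered[0].start_date, ordered[0].end_date
    for s in ordered[1:]:
        gap = (s.start_date - cur_end).days - 1
        if gap <= max_gap_days:
            if s.end_date > cur_end:
                cur_end = s.end_date
        else:
            out.append(EnrollmentSpell(pid, cur_start, cur_end))
            cur_start, cur_end = s.start_date, s.end_date
    out.append(EnrollmentSpell(pid, cur_start, cur_end))
    return out


# ---------------------------------------------------------------------------
# delimited-file I/O

_FILES = {
    "persons": "persons.csv",
    "enrollment": "enrollment.csv",
    "inpatient": "inpatient.csv",
    "outpatient": "outpatient.csv",
    "prescriptions": "prescriptions.csv",
    "procedures": "procedures.csv",
}
_OPTIONAL_FILES = {"exclusion_flags": "exclusion_flags.csv"}


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    s = str(value).strip()
    return date.fromisoformat(s)


def _parse_opt_date(value) -> date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    return date.fromisoformat(s)


def _split_multi(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return ()
    return tuple(part.strip() for part in s.split(";") if part.strip())


def _read_table(dir_path: Path, fname: str) -> pd.DataFrame:
    path = dir_path / fname
    if not path.exists():
        raise FileNotFoundError(f"required claims file missing: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_claims(dir_path: str | Path, strict: bool = False) -> ClaimsDataset:
    """Read a claims directory into a typed :class:`ClaimsDataset`.

    Rows failing parsing or invariant checks land in ``dataset.rejects``;
    with ``strict=True`` any rejected row raises :class:`ClaimsValidationError`.
    """
    dir_path = Path(dir_path)
    ds = ClaimsDataset()

    df = _read_table(dir_path, _FILES["persons"])
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            p = Person(
                person_id=str(row.person_id),
                birth_date=_parse_date(row.birth_date),
                sex=str(row.sex).strip().upper(),
                death_date=_parse_opt_date(getattr(row, "death_date", None)),
            )
            if p.sex not in ("F", "M"):
                raise ValueError(f"sex must be F or M, got {p.sex!r}")
            ds.add_person(p)
        except Exception as exc:
            ds.rejects.append(RejectedRow("persons", i, str(exc)))

    def _rows(table: str):
        frame = _read_table(dir_path, _FILES[table])
        for i, row in enumerate(frame.itertuples(index=False)):
            yield i, row

    for i, row in _rows("enrollment"):
        try:
            s = EnrollmentSpell(str(row.person_id), _parse_date(row.start_date), _parse_date(row.end_date))
            if s.start_date > s.end_date:
                raise ValueError("start_date after end_date")
            ds.persons[s.person_id].enrollment.append(s)
        except Exception as exc:
            ds.rejects.append(RejectedRow("enrollment", i, str(exc)))

    for i, row in _rows("inpatient"):
        try:
            s = InpatientStay(
                str(row.person_id),
                _parse_date(row.admission_date),
                _parse_date(row.discharge_date),
                str(row.primary_dx).strip(),
                _split_multi(row.secondary_dx),
                _split_multi(row.admission_dx),
            )
            if s.admission_date > s.discharge_date:
                raise ValueError("discharge before admission")
            ds.persons[s.person_id].inpatient.append(s)
        except Exception as exc:
            ds.rejects.append(RejectedRow("inpatient", i, str(exc)))

    for i, row in _rows("outpatient"):
        try:
            v = OutpatientVisit(
                str(row.person_id),
                _parse_date(row.visit_date),
                str(row.primary_dx).strip(),
                _split_multi(row.secondary_dx),
                str(row.setting).strip(),
            )
            if v.setting not in SETTINGS:
                raise ValueError(f"unknown setting {v.setting!r}")
            ds.persons[v.person_id].outpatient.append(v)
        except Exception as exc:
            ds.rejects.append(RejectedRow("outpatient", i, str(exc)))

    for i, row in _rows("prescriptions"):
        try:
            raw_ds = getattr(row, "days_supplied", "")
            f = PrescriptionFill(
                str(row.person_id),
                _parse_date(row.fill_date),
                str(row.drug_class).strip(),
                str(getattr(row, "drug_name", "")).strip(),
                int(raw_ds) if str(raw_ds).strip() else None,
            )
            if f.drug_class not in DRUG_CLASSES:
                raise ValueError(f"unknown drug_class {f.drug_class!r}")
            ds.persons[f.person_id].prescriptions.append(f)
        except Exception as exc:
            ds.rejects.append(RejectedRow("prescriptions", i, str(exc)))

    for i, row in _rows("procedures"):
        try:
            pr = ProcedureClaim(str(row.person_id), _parse_date(row.service_date), str(row.procedure_code).strip())
            ds.persons[pr.person_id].procedures.append(pr)
        except Exception as exc:
            ds.rejects.append(RejectedRow("procedures", i, str(exc)))

    flags_path = dir_path / _OPTIONAL_FILES["exclusion_flags"]
    if flags_path.exists():
        frame = pd.read_csv(flags_path, dtype=str, keep_default_na=False)
        for i, row in enumerate(frame.itertuples(index=False)):
            try:
                fl = ExclusionFlag(
                    str(row.person_id), str(row.flag).strip(),
                    _parse_date(row.start_date), _parse_date(row.end_date),
                )
                if fl.flag not in EXCLUSION_FLAGS:
                    raise ValueError(f"unknown exclusion flag {fl.flag!r}")
                ds.persons[fl.person_id].exclusion_flags.append(fl)
            except Exception as exc:
                ds.rejects.append(RejectedRow("exclusion_flags", i, str(exc)))

    # birth_date must not postdate any claim
    for pid, pc in ds.persons.items():
        dates: list[date] = [s.start_date for s in pc.enrollment]
        dates += [s.admission_date for s in pc.inpatient]
        dates += [v.visit_date for v in pc.outpatient]
        dates += [f.fill_date for f in pc.prescriptions]
        dates += [p.service_date for p in pc.procedures]
        if dates and min(dates) < pc.person.birth_date:
            ds.rejects.append(RejectedRow("persons", -1, f"claim predates birth for {pid}"))

    ds.sort_claims()
    if strict and ds.rejects:
        raise ClaimsValidationError(
            f"{len(ds.rejects)} rejected rows (first: {ds.rejects[0]})"
        )
    return ds


def _join_multi(values: Iterable[str]) -> str:
    return ";".join(values)


def write_claims(ds: ClaimsDataset, dir_path: str | Path) -> None:
    """Write a dataset back to the delimited interchange format (round-trips)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    ds.sort_claims()

    persons_rows, enr, inp, outp, rx, proc, flags = [], [], [], [], [], [], []
    for pid in sorted(ds.persons):
        pc = ds.persons[pid]
        p = pc.person
        persons_rows.append(
            dict(person_id=p.person_id, birth_date=p.birth_date.isoformat(), sex=p.sex,
                 death_date=p.death_date.isoformat() if p.death_date else "")
        )
        enr += [dict(person_id=pid, start_date=s.start_date.isoformat(), end_date=s.end_date.isoformat())
                for s in pc.enrollment]
        inp += [dict(person_id=pid, admission_date=s.admission_date.isoformat(),
                     discharge_date=s.discharge_date.isoformat(), primary_dx=s.primary_dx,
                     secondary_dx=_join_multi(s.secondary_dx), admission_dx=_join_multi(s.admission_dx))
                for s in pc.inpatient]
        outp += [dict(person_id=pid, visit_date=v.visit_date.isoformat(), primary_dx=v.primary_dx,
                      secondary_dx=_join_multi(v.secondary_dx), setting=v.setting)
                 for v in pc.outpatient]
        rx += [dict(person_id=pid, fill_date=f.fill_date.isoformat(), drug_class=f.drug_class,
                    drug_name=f.drug_name,
                    days_supplied="" if f.days_supplied is None else str(f.days_supplied))
               for f in pc.prescriptions]
        proc += [dict(person_id=pid, service_date=p2.service_date.isoformat(),
                      procedure_code=p2.procedure_code)
                 for p2 in pc.procedures]
        flags += [dict(person_id=pid, flag=fl.flag, start_date=fl.start_date.isoformat(),
                       end_date=fl.end_date.isoformat())
                  for fl in pc.exclusion_flags]

    def _dump(rows, fname, columns):
        pd.DataFrame(rows, columns=columns).to_csv(dir_path / fname, index=False)

    _dump(persons_rows, "persons.csv", ["person_id", "birth_date", "sex", "death_date"])
    _dump(enr, "enrollment.csv", ["person_id", "start_date", "end_date"])
    _dump(inp, "inpatient.csv",
          ["person_id", "admission_date", "discharge_date", "primary_dx", "secondary_dx", "admission_dx"])
    _dump(outp, "outpatient.csv", ["person_id", "visit_date", "primary_dx", "secondary_dx", "setting"])
    _dump(rx, "prescriptions.csv", ["person_id", "fill_date", "drug_class", "drug_name", "days_supplied"])
    _dump(proc, "procedures.csv", ["person_id", "service_date", "procedure_code"])
    if flags:
        _dump(flags, "exclusion_flags.csv", ["person_id", "flag", "start_date", "end_date"])


def covered(spells: Sequence[EnrollmentSpell], start: date, end: date) -> bool:
    """True iff the closed interval [start, end] lies within a single spell."""
    for s in spells:
        if s.start_date <= start and end <= s.end_date:
            return True
    return False


ONE_DAY = timedelta(days=1)
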