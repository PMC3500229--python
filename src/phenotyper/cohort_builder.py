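"""New-user cohort construction.

A person enters the cohort on the first day they satisfy every inclusion and
exclusion criterion while filling a qualifying study-drug (psychotropic)
prescription: age 6-24, a full baseline year of enrollment (lapses of at most
7 days tolerated), some medical care utilization in that year, no medical
care ever indicating diabetes, none of the exclusion conditions active, not
hospitalized currently or discharged within the past 30 days, and a 365-day
study-drug washout — with the allowance that fills confined to the 90 days
before the qualifying fill do not disqualify it provided the earliest fill
of that cluster itself had a clean 365-day washout (patients restarting
shortly after a hospital discharge).

Follow-up runs from the day after the qualifying fill to the earliest of:
study end, the day before the 25th birthday, disenrollment, death, failure
of study criteria (an exclusion condition beginning during follow-up), or
365 days after the last day of current use of the study drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Callable, Sequence

from .claims_model import (
    ClaimsDataset,
    PersonClaims,
    PrescriptionFill,
    covered,
    normalize_enrollment,
)
from .codesets import CodeRegistry
from .config import DEFAULT_CONFIG, PipelineConfig

__all__ = [
    "CohortMember",
    "EligibilityVerdict",
    "check_baseline_eligibility",
    "find_qualifying_initiation",
    "compute_followup_end",
    "build_cohort",
    "age_years",
]

CENSOR_REASONS = (
    "study_end",
    "age_25",
    "disenrollment",
    "death",
    "criteria_failure",
    "drug_discontinuation_365",
)


def age_years(birth_date: date, on: date) -> int:
    """Completed years of age on a calendar day (Feb 29 births age on Mar 1)."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _birthday(birth_date: date, years: int) -> date:
    try:
        return birth_date.replace(year=birth_date.year + years)
    except ValueError:  # Feb 29
        return date(birth_date.year + years, 3, 1)


@dataclass(frozen=True, slots=True)
class CohortMember:
    person_id: str
    time_zero: date            # the qualifying fill day
    qualifying_fill_date: date
    followup_start: date       # time_zero + 1 day
    followup_end: date
    censor_reason: str


@dataclass(frozen=True, slots=True)
class EligibilityVerdict:
    eligible: bool
    reasons: tuple[str, ...] = ()


def check_baseline_eligibility(
    pc: PersonClaims,
    candidate_date: date,
    registry: CodeRegistry,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> EligibilityVerdict:
    """Evaluate every baseline criterion on one candidate day.

    The verdict carries one reason code per failed criterion, so planted
    single-violation probes can be checked for exactly their violation.
    """
    reasons: list[str] = []
    c = candidate_date
    lookback_start = c - timedelta(days=config.baseline_days)

    age = age_years(pc.person.birth_date, c)
    if not (config.min_age_years <= age < config.max_age_years):
        reasons.append("age")

    spells = normalize_enrollment(pc.enrollment, config.max_enrollment_gap_days)
    if not covered(spells, lookback_start, c):
        reasons.append("enrollment_gap")

    day_before = c - timedelta(days=1)
    utilization = (
        any(lookback_start <= s.admission_date <= day_before for s in pc.inpatient)
        or any(lookback_start <= v.visit_date <= day_before for v in pc.outpatient)
        or any(lookback_start <= f.fill_date <= day_before for f in pc.prescriptions)
        or any(lookback_start <= p.service_date <= day_before for p in pc.procedures)
    )
    if not utilization:
        reasons.append("no_utilization")

    if _prior_diabetes_care(pc, c, registry):
        reasons.append("prior_diabetes_care")

    for fl in pc.exclusion_flags:
        if fl.start_date <= c <= fl.end_date:
            reasons.append(f"exclusion_flag:{fl.flag}")

    recent_start = c - timedelta(days=config.recent_hospital_days)
    for s in pc.inpatient:
        if s.admission_date <= c <= s.discharge_date:
            reasons.append("in_hospital")
            break
        if recent_start <= s.discharge_date <= day_before:
            reasons.append("recent_hospital_discharge")
            break

    return EligibilityVerdict(eligible=not reasons, reasons=tuple(reasons))


def _prior_diabetes_care(pc: PersonClaims, on_or_before: date, registry: CodeRegistry) -> bool:
    for s in pc.inpatient:
        if s.admission_date <= on_or_before:
            if registry.is_diabetes_dx(s.primary_dx) or any(
                registry.is_diabetes_dx(d) for d in s.secondary_dx + s.admission_dx
            ):
                return True
    for v in pc.outpatient:
        if v.visit_date <= on_or_before:
            if registry.is_diabetes_dx(v.primary_dx) or any(
                registry.is_diabetes_dx(d) for d in v.secondary_dx
            ):
                return True
    for f in pc.prescriptions:
        if f.fill_date <= on_or_before and registry.is_diabetes_drug_class(f.drug_class):
            return True
    return False


def find_qualifying_initiation(
    fills: Sequence[PrescriptionFill],
    eligible_on: Callable[[date], bool],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> PrescriptionFill | None:
    """First study-drug fill that defines a new initiation.

    ``fills`` must be the person's study-drug fills sorted by date;
    ``eligible_on`` is the baseline-eligibility oracle for a candidate day.
    A fill F qualifies when F falls on an eligible day and either (a) no
    study-drug fill lies in [F-365, F-1], or (b) every such fill lies within
    [F-90, F-1] and the earliest fill of that cluster itself has no
    study-drug fill in its preceding 365 days.
    """
    washout = timedelta(days=config.washout_days)
    allowance = timedelta(days=config.allowance_days)
    dates = [f.fill_date for f in fills]
    for idx, f in enumerate(fills):
        F = f.fill_date
        prior = [d for d in dates[:idx] if F - washout <= d < F]
        if prior:
            if not all(d >= F - allowance for d in prior):
                continue
            cluster_start = min(prior)
            if any(cluster_start - washout <= d <= cluster_start - timedelta(days=1) for d in dates if d < cluster_start):
                continue
        if eligible_on(F):
            return f
    return None


def compute_followup_end(
    pc: PersonClaims,
    qualifying_fill_date: date,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[date, str]:
    """Earliest applicable censoring bound and its reason.

    The "current use" chain starts at the qualifying fill; each study-drug
    fill extends coverage to fill date + days supplied (default 30) + grace,
    and a subsequent fill continues the chain only if it starts before
    coverage runs out.  Discontinuation censors 365 days after the chain end.
    """
    start = qualifying_fill_date + timedelta(days=1)
    bounds: list[tuple[date, int, str]] = [(config.study_end, 0, "study_end")]

    bday25 = _birthday(pc.person.birth_date, config.max_age_years)
    bounds.append((bday25 - timedelta(days=1), 1, "age_25"))

    spells = normalize_enrollment(pc.enrollment, config.max_enrollment_gap_days)
    for s in spells:
        if s.start_date <= qualifying_fill_date <= s.end_date:
            bounds.append((s.end_date, 2, "disenrollment"))
            break

    if pc.person.death_date is not None:
        bounds.append((pc.person.death_date, 3, "death"))

    for fl in pc.exclusion_flags:
        if fl.start_date > qualifying_fill_date:
            bounds.append((fl.start_date, 4, "criteria_failure"))
            break

    supply = timedelta(days=config.days_supplied_default)
    grace = timedelta(days=config.grace_period_days)
    chain_end = qualifying_fill_date + supply
    for f in pc.prescriptions:
        if f.drug_class != "study_psychotropic" or f.fill_date <= qualifying_fill_date:
            continue
        if f.fill_date <= chain_end + grace:
            this_supply = timedelta(days=f.days_supplied) if f.days_supplied else supply
            chain_end = max(chain_end, f.fill_date + this_supply)
    bounds.append((chain_end + timedelta(days=config.discontinuation_days), 5, "drug_discontinuation_365"))

    end, _, reason = min(bounds, key=lambda b: (b[0], b[1]))
    if end < start:  # degenerate zero-length follow-up
        end = start
    return end, reason


def build_cohort(
    ds: ClaimsDataset,
    registry: CodeRegistry,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[CohortMember]:
    """One :class:`CohortMember` per person with a qualifying initiation."""
    members: list[CohortMember] = []
    for pid in ds.person_ids():
        pc = ds.get(pid)
        study_fills = [f for f in pc.prescriptions if f.drug_class == "study_psychotropic"]
        if not study_fills:
            continue

        def eligible_on(d: date, _pc=pc) -> bool:
            if not (config.study_start <= d <= config.study_end):
                return False
            return check_baseline_eligibility(_pc, d, registry, config).eligible

        fill = find_qualifying_initiation(study_fills, eligible_on, config)
        if fill is None:
            continue
        end, reason = compute_followup_end(pc, fill.fill_date, config)
        members.append(
            CohortMember(
                person_id=pid,
                time_zero=fill.fill_date,
                qualifying_fill_date=fill.fill_date,
                followup_start=fill.fill_date + timedelta(days=1),
                followup_end=end,
                censor_reason=reason,
            )
        )
    return members


# ---------------------------------------------------------------------------
# cohort I/O

def write_cohort(members: Sequence[CohortMember], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [dict(person_id=m.person_id, time_zero=m.time_zero.isoformat(),
              qualifying_fill_date=m.qualifying_fill_date.isoformat(),
              followup_start=m.followup_start.isoformat(),
              followup_end=m.followup_end.isoformat(),
              censor_reason=m.censor_reason)
         for m in members],
        columns=["person_id", "time_zero", "qualifying_fill_date",
                 "followup_start", "followup_end", "censor_reason"],
    ).to_csv(path, index=False)


def read_cohort(path) -> list[CohortMember]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        CohortMember(
            person_id=str(r.person_id),
            time_zero=date.fromisoformat(r.time_zero),
            qualifying_fill_date=date.fromisoformat(r.qualifying_fill_date),
            followup_start=date.fromisoformat(r.followup_start),
            followup_end=date.fromisoformat(r.followup_end),
            censor_reason=str(r.censor_reason),
        )
        for r in df.itertuples(index=False)
    ]
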