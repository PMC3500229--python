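"""The automated case definition for newly diagnosed diabetes.

The engine scans a cohort member's follow-up window for diabetes-related
medical care encounters — hospitalizations with a primary or secondary
diabetes diagnosis, outpatient visits with a primary diabetes diagnosis,
and filled prescriptions for diabetes medications — and adjudicates the
*first* such encounter:

* a hospitalization with a primary discharge diagnosis of diabetes meets the
  definition outright;
* any other encounter type is first screened for a polycystic-ovarian-
  syndrome diagnosis within ±120 days of the initial index date (PCOS is
  routinely treated with oral hypoglycemics and is the dominant source of
  false-positive prescription signals in reproductive-age women), then must
  be confirmed by a later claim of a different kind — a diagnosis by a
  prescription, a prescription by a diagnosis or by a second prescription
  plus a diabetes-management procedure.

Two variants exist.  The *primary* definition requires the confirmations
above (it essentially identifies pharmacologically treated diabetes).  The
*secondary* definition relaxes it to catch diabetes managed without drugs:
secondary-inpatient encounters need no confirmation and an outpatient
diagnosis can be confirmed by a glycosylated-hemoglobin test alone.  By
construction every primary-positive member is secondary-positive.

A met case receives a final index date — reset to the earliest
diabetes-related procedure in the 29 days before the initial encounter,
mirroring a diagnosis made once test results returned — and a subtype:
type 1 when an insulin fill occurs within 120 days of the final index date
with at most one oral-hypoglycemic fill in that interval, else type 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

from .claims_model import (
    EncounterEvidence,
    InpatientStay,
    PersonClaims,
)
from .codesets import CodeRegistry
from .cohort_builder import CohortMember
from .config import DEFAULT_CONFIG, PipelineConfig

__all__ = [
    "CaseRecord",
    "hospital_stay_period",
    "extract_diabetes_encounters",
    "pcos_excluded",
    "confirm_encounter",
    "assign_final_index",
    "classify_subtype",
    "apply_definition",
    "apply_definition_all",
]

VARIANTS = ("primary", "secondary")
CONFIRMATIONS = (
    "not_required",
    "by_prescription",
    "by_diagnosis",
    "by_rx_plus_procedure",
    "by_hba1c_procedure",
    "none_found",
)
_PRECEDENCE = {"inpatient_primary": 0, "inpatient_secondary": 1, "outpatient": 2, "prescription": 3}


@dataclass(frozen=True, slots=True)
class CaseRecord:
    """The engine's verdict for one cohort member."""

    person_id: str
    met_definition: bool
    definition_variant: str
    initial_index_date: date | None = None
    final_index_date: date | None = None
    encounter_type: str | None = None
    confirmation: str | None = None
    excluded_reason: str = "none"        # none | pcos_window
    subtype: str = "not_applicable"      # type1 | type2 | not_applicable
    evidence: tuple[str, ...] = ()


def hospital_stay_period(stay: InpatientStay) -> tuple[date, date]:
    """Closed interval from the day before admission through the day after discharge."""
    return stay.admission_date - timedelta(days=1), stay.discharge_date + timedelta(days=1)


def _dx_visit_on(pc: PersonClaims, day: date, registry: CodeRegistry) -> bool:
    """An ED/outpatient visit carrying any diabetes diagnosis on the given day."""
    for v in pc.outpatient:
        if v.visit_date == day and v.setting in ("outpatient", "emergency"):
            if registry.is_diabetes_dx(v.primary_dx) or any(
                registry.is_diabetes_dx(d) for d in v.secondary_dx
            ):
                return True
    return False


def _stay_index_date(stay: InpatientStay, pc: PersonClaims, registry: CodeRegistry,
                     followup_start: date) -> date:
    """Admission date, or the prior day if an ED/outpatient visit with a
    diabetes diagnosis fell on that day (and it still lies in follow-up)."""
    t = stay.admission_date
    prior = t - timedelta(days=1)
    if prior >= followup_start and _dx_visit_on(pc, prior, registry):
        return prior
    return t


def _no_pcos_near(pc: PersonClaims, t: date, registry: CodeRegistry, window: int) -> bool:
    return not _pcos_dx_in(pc, t - timedelta(days=window), t + timedelta(days=window), registry)


def _pcos_dx_in(pc: PersonClaims, lo: date, hi: date, registry: CodeRegistry) -> bool:
    for v in pc.outpatient:
        if lo <= v.visit_date <= hi:
            if registry.is_pcos_dx(v.primary_dx) or any(registry.is_pcos_dx(d) for d in v.secondary_dx):
                return True
    for s in pc.inpatient:
        if lo <= s.admission_date <= hi:
            if registry.is_pcos_dx(s.primary_dx) or any(
                registry.is_pcos_dx(d) for d in s.secondary_dx + s.admission_dx
            ):
                return True
    return False


def extract_diabetes_encounters(
    pc: PersonClaims,
    followup: tuple[date, date],
    registry: CodeRegistry,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[EncounterEvidence]:
    """All diabetes-related medical care encounters during follow-up.

    Output is sorted by initial index date, ties broken by evidence strength
    (inpatient-primary, inpatient-secondary, outpatient, prescription).
    Prescription encounters are suppressed when a PCOS diagnosis falls within
    ±120 days of the fill; outpatient visits inside any hospital stay period
    are attributed to the hospitalization, not emitted as outpatient
    encounters.
    """
    lo, hi = followup
    pid = pc.person.person_id
    out: list[EncounterEvidence] = []
    periods = [hospital_stay_period(s) for s in pc.inpatient]

    for s in pc.inpatient:
        if not (lo <= s.admission_date <= hi):
            continue
        t = _stay_index_date(s, pc, registry, lo)
        if registry.is_primary_inpatient_dx(s.primary_dx):
            out.append(EncounterEvidence(pid, "inpatient_primary", t,
                                         f"inpatient:{s.admission_date.isoformat()}"))
        elif any(registry.is_diabetes_dx(d) for d in s.secondary_dx + s.admission_dx):
            out.append(EncounterEvidence(pid, "inpatient_secondary", t,
                                         f"inpatient:{s.admission_date.isoformat()}"))

    # physician encounter with primary diabetes dx during some hospital stay period
    for v in pc.outpatient:
        if v.setting != "physician_inpatient" or not registry.is_diabetes_dx(v.primary_dx):
            continue
        for s in pc.inpatient:
            p_lo, p_hi = hospital_stay_period(s)
            if p_lo <= v.visit_date <= p_hi and lo <= s.admission_date <= hi:
                t = _stay_index_date(s, pc, registry, lo)
                out.append(EncounterEvidence(pid, "inpatient_secondary", t,
                                             f"physician_inpatient:{v.visit_date.isoformat()}"))
                break

    for v in pc.outpatient:
        if v.setting not in ("outpatient", "emergency"):
            continue
        if not (lo <= v.visit_date <= hi) or not registry.is_diabetes_dx(v.primary_dx):
            continue
        if any(p_lo <= v.visit_date <= p_hi for p_lo, p_hi in periods):
            continue
        out.append(EncounterEvidence(pid, "outpatient", v.visit_date,
                                     f"outpatient:{v.visit_date.isoformat()}"))

    for f in pc.prescriptions:
        if not (lo <= f.fill_date <= hi) or not registry.is_diabetes_drug_class(f.drug_class):
            continue
        if _no_pcos_near(pc, f.fill_date, registry, config.pcos_window_days):
            out.append(EncounterEvidence(pid, "prescription", f.fill_date,
                                         f"prescription:{f.fill_date.isoformat()}"))

    out.sort(key=lambda e: (e.event_date, _PRECEDENCE[e.encounter_type]))
    # one encounter per (type, index date): duplicates add no information
    seen: set[tuple[str, date]] = set()
    deduped: list[EncounterEvidence] = []
    for e in out:
        key = (e.encounter_type, e.event_date)
        if key not in seen:
            seen.add(key)
            deduped.append(e)
    return deduped


def pcos_excluded(pc: PersonClaims, t_x: date, registry: CodeRegistry,
                  config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """True iff any PCOS diagnosis (any position, any setting) lies in
    the closed interval [t_x-120, t_x+120]."""
    w = timedelta(days=config.pcos_window_days)
    return _pcos_dx_in(pc, t_x - w, t_x + w, registry)


def _later_diabetes_dx_dates(pc: PersonClaims, after: date, until: date,
                             registry: CodeRegistry, *, inpatient_only: bool = False) -> date | None:
    best: date | None = None
    for s in pc.inpatient:
        if after < s.admission_date <= until:
            if registry.is_diabetes_dx(s.primary_dx) or any(
                registry.is_diabetes_dx(d) for d in s.secondary_dx + s.admission_dx
            ):
                if best is None or s.admission_date < best:
                    best = s.admission_date
    if not inpatient_only:
        for v in pc.outpatient:
            if after < v.visit_date <= until:
                if registry.is_diabetes_dx(v.primary_dx) or any(
                    registry.is_diabetes_dx(d) for d in v.secondary_dx
                ):
                    if best is None or v.visit_date < best:
                        best = v.visit_date
    return best


def confirm_encounter(
    encounter: EncounterEvidence,
    pc: PersonClaims,
    registry: CodeRegistry,
    variant: str,
    window_end: date,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[str, list[str]]:
    """Confirmation verdict for a non-primary-inpatient encounter.

    Returns the confirmation category and the audit trail of confirming
    events.  Confirming events must fall strictly after the initial index
    date and on or before ``window_end``; the diabetes-management procedure
    of the prescription pathway may share a date with the second fill.
    """
    t = encounter.event_date
    kind = encounter.encounter_type
    trail: list[str] = []

    def first_fill_after(after: date) -> date | None:
        for f in pc.prescriptions:
            if after < f.fill_date <= window_end and registry.is_diabetes_drug_class(f.drug_class):
                return f.fill_date
        return None

    if kind == "inpatient_primary":
        return "not_required", trail

    if kind == "inpatient_secondary":
        if variant == "secondary":
            return "not_required", trail
        d = first_fill_after(t)
        if d is not None:
            trail.append(f"confirm_rx:{d.isoformat()}")
            return "by_prescription", trail
        d = _later_diabetes_dx_dates(pc, t, window_end, registry)
        if d is not None:
            trail.append(f"confirm_dx:{d.isoformat()}")
            return "by_diagnosis", trail
        return "none_found", trail

    if kind == "outpatient":
        d = first_fill_after(t)
        if d is not None:
            trail.append(f"confirm_rx:{d.isoformat()}")
            return "by_prescription", trail
        d = _later_diabetes_dx_dates(pc, t, window_end, registry, inpatient_only=True)
        if d is not None:
            trail.append(f"confirm_dx:{d.isoformat()}")
            return "by_diagnosis", trail
        if variant == "secondary":
            for p in pc.procedures:
                if t < p.service_date <= window_end and registry.is_hba1c_proc(p.procedure_code):
                    trail.append(f"confirm_hba1c:{p.service_date.isoformat()}")
                    return "by_hba1c_procedure", trail
        return "none_found", trail

    if kind == "prescription":
        d = _later_diabetes_dx_dates(pc, t, window_end, registry)
        if d is not None:
            trail.append(f"confirm_dx:{d.isoformat()}")
            return "by_diagnosis", trail
        second = first_fill_after(t)
        if second is not None:
            proc_date = None
            for p in pc.procedures:
                if t < p.service_date <= window_end and registry.is_management_proc(p.procedure_code):
                    proc_date = p.service_date
                    break
            if proc_date is not None and not _menses_dx_in(pc, t + timedelta(days=1), window_end, registry):
                trail.append(f"confirm_rx:{second.isoformat()}")
                trail.append(f"confirm_proc:{proc_date.isoformat()}")
                return "by_rx_plus_procedure", trail
        return "none_found", trail

    raise ValueError(f"unknown encounter type {kind!r}")


def _menses_dx_in(pc: PersonClaims, lo: date, hi: date, registry: CodeRegistry) -> bool:
    for v in pc.outpatient:
        if lo <= v.visit_date <= hi:
            if registry.is_menses_abnormal_dx(v.primary_dx) or any(
                registry.is_menses_abnormal_dx(d) for d in v.secondary_dx
            ):
                return True
    for s in pc.inpatient:
        if lo <= s.admission_date <= hi:
            if registry.is_menses_abnormal_dx(s.primary_dx) or any(
                registry.is_menses_abnormal_dx(d) for d in s.secondary_dx + s.admission_dx
            ):
                return True
    return False


def assign_final_index(t_x_initial: date, pc: PersonClaims, registry: CodeRegistry,
                       config: PipelineConfig = DEFAULT_CONFIG) -> date:
    """Earliest diabetes-related procedure in [t_x-29, t_x-1], else t_x."""
    lo = t_x_initial - timedelta(days=config.index_reset_days)
    hi = t_x_initial - timedelta(days=1)
    best: date | None = None
    for p in pc.procedures:
        if lo <= p.service_date <= hi and registry.is_index_reset_proc(p.procedure_code):
            if best is None or p.service_date < best:
                best = p.service_date
    return best if best is not None else t_x_initial


def classify_subtype(pc: PersonClaims, final_index: date, registry: CodeRegistry,
                     config: PipelineConfig = DEFAULT_CONFIG) -> str:
    """Type 1 iff an insulin fill lies in [final_index, final_index+120] with
    at most one oral-hypoglycemic fill in that interval; otherwise type 2."""
    hi = final_index + timedelta(days=config.subtype_window_days)
    insulin_classes = {"insulin"}
    if config.adjunct_counts_as_insulin:
        insulin_classes.add("insulin_adjunct")
    has_insulin = False
    n_oral = 0
    for f in pc.prescriptions:
        if final_index <= f.fill_date <= hi:
            if f.drug_class in insulin_classes:
                has_insulin = True
            elif f.drug_class == "oral_hypoglycemic":
                n_oral += 1
    return "type1" if has_insulin and n_oral <= 1 else "type2"


def apply_definition(
    member: CohortMember,
    pc: PersonClaims,
    registry: CodeRegistry,
    variant: str = "primary",
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CaseRecord:
    """Adjudicate one cohort member; always returns exactly one record.

    The first encounter during follow-up fixes the outcome: if it is
    excluded or unconfirmed the member is classified not-met (no fall-through
    to later encounters unless ``config.fall_through`` is set).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    followup = (member.followup_start, member.followup_end)
    encounters = extract_diabetes_encounters(pc, followup, registry, config)
    if not encounters:
        return CaseRecord(member.person_id, False, variant)

    candidates = encounters if config.fall_through else encounters[:1]
    record = None
    for enc in candidates:
        record = _adjudicate_encounter(member, pc, enc, registry, variant, config)
        if record.met_definition:
            return record
    return record  # the first (or last attempted) failure


def _adjudicate_encounter(member, pc, enc, registry, variant, config) -> CaseRecord:
    t = enc.event_date
    evidence = [f"{enc.encounter_type}:{t.isoformat()}"]

    if enc.encounter_type != "inpatient_primary":
        if pcos_excluded(pc, t, registry, config):
            return CaseRecord(
                member.person_id, False, variant, initial_index_date=t,
                encounter_type=enc.encounter_type, excluded_reason="pcos_window",
                evidence=tuple(evidence),
            )
        window_end = member.followup_end
        if config.confirmation_window_days is not None:
            window_end = min(window_end, t + timedelta(days=config.confirmation_window_days))
        confirmation, trail = confirm_encounter(enc, pc, registry, variant, window_end, config)
        evidence += trail
        if confirmation == "none_found":
            return CaseRecord(
                member.person_id, False, variant, initial_index_date=t,
                encounter_type=enc.encounter_type, confirmation="none_found",
                evidence=tuple(evidence),
            )
    else:
        confirmation = "not_required"

    final = assign_final_index(t, pc, registry, config)
    if final != t:
        evidence.append(f"index_reset:{final.isoformat()}")
    subtype = classify_subtype(pc, final, registry, config)
    return CaseRecord(
        member.person_id, True, variant,
        initial_index_date=t, final_index_date=final,
        encounter_type=enc.encounter_type, confirmation=confirmation,
        subtype=subtype, evidence=tuple(evidence),
    )


def apply_definition_all(
    members: Sequence[CohortMember],
    ds,
    registry: CodeRegistry,
    variant: str = "primary",
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[CaseRecord]:
    return [
        apply_definition(m, ds.get(m.person_id), registry, variant, config)
        for m in members
    ]


# ---------------------------------------------------------------------------
# case-record I/O

def write_cases(cases: Sequence[CaseRecord], path) -> None:
    import pandas as pd

    rows = []
    for c in cases:
        rows.append(dict(
            person_id=c.person_id,
            met_definition=str(c.met_definition).lower(),
            definition_variant=c.definition_variant,
            initial_index_date=c.initial_index_date.isoformat() if c.initial_index_date else "",
            final_index_date=c.final_index_date.isoformat() if c.final_index_date else "",
            encounter_type=c.encounter_type or "",
            confirmation=c.confirmation or "",
            excluded_reason=c.excluded_reason,
            subtype=c.subtype,
            evidence="|".join(c.evidence),
        ))
    pd.DataFrame(rows, columns=[
        "person_id", "met_definition", "definition_variant", "initial_index_date",
        "final_index_date", "encounter_type", "confirmation", "excluded_reason",
        "subtype", "evidence",
    ]).to_csv(path, index=False)


def read_cases(path) -> list[CaseRecord]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: list[CaseRecord] = []
    for r in df.itertuples(index=False):
        out.append(CaseRecord(
            person_id=str(r.person_id),
            met_definition=str(r.met_definition).lower() == "true",
            definition_variant=str(r.definition_variant),
            initial_index_date=date.fromisoformat(r.initial_index_date) if str(r.initial_index_date).strip() else None,
            final_index_date=date.fromisoformat(r.final_index_date) if str(r.final_index_date).strip() else None,
            encounter_type=str(r.encounter_type) or None,
            confirmation=str(r.confirmation) or None,
            excluded_reason=str(r.excluded_reason) or "none",
            subtype=str(r.subtype) or "not_applicable",
            evidence=tuple(str(r.evidence).split("|")) if str(r.evidence).strip() else (),
        ))
    return out
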