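"""Seeded generator of Medicaid-like claims streams with planted ground truth.

Each synthetic person receives a baseline year of enrollment, some baseline
medical care, and a qualifying psychotropic initiation, then a scenario-
specific claims stream covering the misclassification taxonomy a chart
review would encounter: canonical incident type 1 and type 2 diabetes care
sequences, diabetes managed by lifestyle alone, prevalent diabetes,
polycystic ovarian syndrome treated with metformin, single rule-out
diagnoses, subthreshold hyperglycemia work-ups, miscoded diagnoses, and
healthy controls.

Ground truth (scenario, true incident status, onset, subtype) stands in for
chart-review adjudication, so the engine and the validation statistics are
testable end to end without any real data.

Randomness is fully reproducible: every person draws from an independent
substream keyed by (seed, person index), so adding a scenario or changing
``n_persons`` never perturbs earlier persons' draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
import numpy as np
from pydantic import BaseModel, Field, model_validator

from .claims_model import (
    ClaimsDataset,
    EnrollmentSpell,
    InpatientStay,
    OutpatientVisit,
    Person,
    PersonClaims,
    PrescriptionFill,
    ProcedureClaim,
)
from .validation_stats import AdjudicationLabel

__all__ = [
    "ScenarioConfig",
    "NoiseConfig",
    "TruthRecord",
    "SCENARIOS",
    "generate",
    "derive_adjudication_labels",
    "eligibility_probe",
    "ELIGIBILITY_PROBE_RULES",
    "write_truth",
    "read_truth",
]

SCENARIOS = (
    "canonical_t1d",
    "canonical_t2d_rx",
    "t2d_lifestyle_only",
    "prevalent_diabetes",
    "pcos_metformin",
    "rule_out_single_dx",
    "subthreshold_hyperglycemia_dx",
    "miscoded_dx",
    "healthy",
)

# Default mix: most diabetes-related encounters are not true incident cases,
# echoing the adjudication composition of a claims catchment.
DEFAULT_MIX: dict[str, float] = {
    "canonical_t1d": 0.08,
    "canonical_t2d_rx": 0.10,
    "t2d_lifestyle_only": 0.05,
    "prevalent_diabetes": 0.05,
    "pcos_metformin": 0.08,
    "rule_out_single_dx": 0.08,
    "subthreshold_hyperglycemia_dx": 0.06,
    "miscoded_dx": 0.04,
    "healthy": 0.46,
}

_DX_URI = "4659"          # common cold-type visit: baseline utilization
_DX_PNEUMONIA = "486"
_DX_T1 = ("25001", "25011", "25013")
_DX_T2 = ("25000", "25002")
_DX_PCOS = "2564"
_PROC_HBA1C = "83036"
_PROC_GLUCOSE = "82947"


class NoiseConfig(BaseModel):
    model_config = {"frozen": True}
    visit_gap_mean_days: float = Field(default=30.0, gt=0)
    confirm_drop_prob: float = Field(default=0.0, ge=0.0, le=1.0)


class ScenarioConfig(BaseModel):
    model_config = {"frozen": True}

    n_persons: int = Field(default=100, ge=0)
    scenario_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MIX))
    study_start: date = date(1996, 1, 1)
    study_end: date = date(2007, 12, 31)
    seed: int = 0
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    leak_prevalent: bool = False
    sex_female_prob: float = Field(default=0.77, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_mix(self):
        unknown = set(self.scenario_mix) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.scenario_mix.values()):
            raise ValueError("scenario probabilities must be non-negative")
        return self


@dataclass(frozen=True, slots=True)
class TruthRecord:
    person_id: str
    scenario: str
    true_incident_diabetes: bool
    true_onset_date: date | None
    true_subtype: str  # type1 | type2 | none
    detail: str = ""   # scenario sub-flag (e.g. rule-out flavor)


def _d(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Uniform integer day offset in [lo, hi]."""
    return int(rng.integers(lo, hi + 1))


def _gap(rng: np.random.Generator, mean_days: float, cap: int = 60) -> int:
    """Visit-gap jitter: geometric with the configured mean, capped."""
    g = int(rng.geometric(1.0 / mean_days))
    return max(1, min(g, cap))


def generate(config: ScenarioConfig) -> tuple[ClaimsDataset, list[TruthRecord]]:
    """Build a claims dataset plus the per-person ground truth.

    Deterministic for a given config; every person is cohort-eligible at
    their psychotropic initiation unless the scenario plants a violation
    (prevalent diabetes claims before time zero, unless ``leak_prevalent``).
    """
    ds = ClaimsDataset()
    truth: list[TruthRecord] = []
    names = sorted(config.scenario_mix)
    probs = np.array([config.scenario_mix[k] for k in names])
    probs = probs / probs.sum()
    span = (config.study_end - config.study_start).days
    master = config.seed % (2**31)

    for i in range(config.n_persons):
        rng = np.random.default_rng([master, i])
        pid = f"P{i:06d}"
        scenario = names[int(rng.choice(len(names), p=probs))]
        t0 = config.study_start + timedelta(days=_d(rng, 400, max(401, span - 900)))
        age_days = _d(rng, int(6 * 365.25), int(24 * 365.25) - 1)
        sex = "F" if rng.random() < config.sex_female_prob else "M"
        if scenario == "pcos_metformin":
            sex = "F"
        person = Person(pid, t0 - timedelta(days=age_days), sex)
        pc = ds.add_person(person)

        enroll_start = t0 - timedelta(days=_d(rng, 380, 480))
        enroll_end = min(t0 + timedelta(days=800), config.study_end + timedelta(days=30))
        pc.enrollment.append(EnrollmentSpell(pid, enroll_start, enroll_end))

        # baseline utilization: one unrelated outpatient visit in the prior year
        pc.outpatient.append(
            OutpatientVisit(pid, t0 - timedelta(days=_d(rng, 30, 300)), _DX_URI)
        )
        # psychotropic maintenance fills keep "current use" alive through follow-up
        for k in range(10):
            pc.prescriptions.append(
                PrescriptionFill(pid, t0 + timedelta(days=28 * k), "study_psychotropic",
                                 "risperidone", 30)
            )

        truth.append(_plant_scenario(pc, scenario, t0, rng, config))

    ds.sort_claims()
    return ds, truth


def _plant_scenario(pc: PersonClaims, scenario: str, t0: date,
                    rng: np.random.Generator, config: ScenarioConfig) -> TruthRecord:
    pid = pc.person.person_id
    noise = config.noise
    onset = t0 + timedelta(days=_d(rng, 30, 150))
    drop_confirm = rng.random() < noise.confirm_drop_prob

    def day(base: date, offset: int) -> date:
        return base + timedelta(days=offset)

    if scenario == "canonical_t1d":
        if rng.random() < 0.5:
            discharge = day(onset, _d(rng, 2, 5))
            pc.inpatient.append(InpatientStay(pid, onset, discharge, _DX_T1[1]))
            first_fill = day(discharge, _gap(rng, 7.0, 14))
        else:
            pc.outpatient.append(OutpatientVisit(pid, onset, _DX_T1[0]))
            first_fill = day(onset, _gap(rng, noise.visit_gap_mean_days))
        if not drop_confirm:
            for k in range(3):
                pc.prescriptions.append(
                    PrescriptionFill(pid, day(first_fill, 30 * k), "insulin", "insulin glargine", 30)
                )
        return TruthRecord(pid, scenario, True, onset, "type1")

    if scenario in ("canonical_t2d_rx", "prevalent_diabetes"):
        leak = scenario == "prevalent_diabetes" and config.leak_prevalent
        if scenario == "prevalent_diabetes" and not leak:
            # visible diabetes care before time zero: fails baseline eligibility
            past = t0 - timedelta(days=_d(rng, 150, 300))
            pc.outpatient.append(OutpatientVisit(pid, past, _DX_T2[0]))
            pc.prescriptions.append(
                PrescriptionFill(pid, day(past, 10), "oral_hypoglycemic", "metformin", 30)
            )
            return TruthRecord(pid, scenario, False, past, "type2")
        # incident-looking type 2 stream (for the leak, chart review alone
        # knows the disease predates the cohort)
        pc.outpatient.append(OutpatientVisit(pid, onset, _DX_T2[0]))
        g = _gap(rng, noise.visit_gap_mean_days)
        if not drop_confirm:
            for k in range(3):
                pc.prescriptions.append(
                    PrescriptionFill(pid, day(onset, g + 30 * k), "oral_hypoglycemic", "metformin", 30)
                )
            pc.procedures.append(ProcedureClaim(pid, day(onset, g), _PROC_HBA1C))
        if rng.random() < 0.3:
            pc.procedures.append(ProcedureClaim(pid, day(onset, -_d(rng, 5, 25)), _PROC_GLUCOSE))
        if scenario == "prevalent_diabetes":
            return TruthRecord(pid, scenario, False, t0 - timedelta(days=200), "type2")
        return TruthRecord(pid, scenario, True, onset, "type2")

    if scenario == "t2d_lifestyle_only":
        pc.outpatient.append(OutpatientVisit(pid, onset, _DX_T2[0]))
        if not drop_confirm:
            pc.procedures.append(
                ProcedureClaim(pid, day(onset, _gap(rng, noise.visit_gap_mean_days)), _PROC_HBA1C)
            )
        return TruthRecord(pid, scenario, True, onset, "type2")

    if scenario == "pcos_metformin":
        for k in range(3):
            pc.prescriptions.append(
                PrescriptionFill(pid, day(onset, 30 * k), "oral_hypoglycemic", "metformin", 30)
            )
        pcos_day = day(onset, _d(rng, -90, 90))
        pc.outpatient.append(OutpatientVisit(pid, pcos_day, _DX_PCOS, ("6264",)))
        return TruthRecord(pid, scenario, False, None, "none")

    if scenario == "rule_out_single_dx":
        pc.outpatient.append(OutpatientVisit(pid, onset, _DX_T2[0]))
        flavor = "lab_rule_out" if rng.random() < 0.5 else "possible"
        if flavor == "lab_rule_out":
            pc.procedures.append(ProcedureClaim(pid, day(onset, 3), _PROC_GLUCOSE))
        return TruthRecord(pid, scenario, False, None, "none", detail=flavor)

    if scenario == "subthreshold_hyperglycemia_dx":
        pc.outpatient.append(OutpatientVisit(pid, onset, _DX_T2[0]))
        pc.procedures.append(ProcedureClaim(pid, day(onset, _d(rng, 1, 7)), _PROC_GLUCOSE))
        return TruthRecord(pid, scenario, False, None, "none")

    if scenario == "miscoded_dx":
        pc.inpatient.append(
            InpatientStay(pid, onset, day(onset, 2), _DX_PNEUMONIA, (_DX_T2[0],))
        )
        return TruthRecord(pid, scenario, False, None, "none")

    if scenario == "healthy":
        return TruthRecord(pid, scenario, False, None, "none")

    raise ValueError(f"unknown scenario {scenario!r}")


_LABEL_MAP = {
    "canonical_t1d": ("incident_diabetes", "type1"),
    "canonical_t2d_rx": ("incident_diabetes", "type2"),
    "t2d_lifestyle_only": ("incident_diabetes", "type2"),
    "prevalent_diabetes": ("prevalent_diabetes", "not_applicable"),
    "pcos_metformin": ("pcos", "not_applicable"),
    "subthreshold_hyperglycemia_dx": ("subthreshold_hyperglycemia", "not_applicable"),
    "miscoded_dx": ("miscoded", "not_applicable"),
    "healthy": ("not_diabetes_other", "not_applicable"),
}


def derive_adjudication_labels(truth: list[TruthRecord]) -> list[AdjudicationLabel]:
    """Map planted scenarios onto the chart-review adjudication vocabulary."""
    labels: list[AdjudicationLabel] = []
    for t in truth:
        if t.scenario == "rule_out_single_dx":
            status = "lab_rule_out" if t.detail == "lab_rule_out" else "possible_diabetes"
            labels.append(AdjudicationLabel(t.person_id, status))
        else:
            status, subtype = _LABEL_MAP[t.scenario]
            labels.append(AdjudicationLabel(t.person_id, status, subtype))
    return labels


# ---------------------------------------------------------------------------
# eligibility probes: one planted violation per person

ELIGIBILITY_PROBE_RULES = (
    "age",
    "enrollment_gap",
    "recent_hospital_discharge",
    "prior_diabetes_care",
    "washout",
    "allowance_90day",
    "none",
)


def eligibility_probe(rule: str, t0: date = date(2000, 6, 15)) -> ClaimsDataset:
    """A one-person dataset violating exactly one cohort criterion.

    ``rule='none'`` is the fully eligible control; ``'washout'`` plants a
    study-drug fill 200 days back (outside the 90-day allowance);
    ``'allowance_90day'`` plants the post-discharge restart the 90-day
    allowance is designed to admit.
    """
    if rule not in ELIGIBILITY_PROBE_RULES:
        raise ValueError(f"unknown probe rule {rule!r}")
    ds = ClaimsDataset()
    pid = f"probe_{rule}"
    birth = t0 - timedelta(days=12 * 365) if rule != "age" else t0 - timedelta(days=5 * 365)
    pc = ds.add_person(Person(pid, birth, "F"))

    if rule == "enrollment_gap":
        # 8-day lapse inside the baseline year
        pc.enrollment.append(EnrollmentSpell(pid, t0 - timedelta(days=420), t0 - timedelta(days=200)))
        pc.enrollment.append(EnrollmentSpell(pid, t0 - timedelta(days=191), t0 + timedelta(days=400)))
    else:
        pc.enrollment.append(EnrollmentSpell(pid, t0 - timedelta(days=420), t0 + timedelta(days=400)))

    pc.outpatient.append(OutpatientVisit(pid, t0 - timedelta(days=100), _DX_URI))

    if rule == "recent_hospital_discharge":
        pc.inpatient.append(
            InpatientStay(pid, t0 - timedelta(days=14), t0 - timedelta(days=10), _DX_PNEUMONIA)
        )
    if rule == "prior_diabetes_care":
        pc.prescriptions.append(
            PrescriptionFill(pid, t0 - timedelta(days=400), "oral_hypoglycemic", "metformin", 30)
        )
    if rule == "washout":
        pc.prescriptions.append(
            PrescriptionFill(pid, t0 - timedelta(days=200), "study_psychotropic", "sertraline", 30)
        )
    if rule == "allowance_90day":
        # hospitalized t0-80 .. t0-35; a fill during the stay is non-qualifying
        # (in hospital), and the restart at t0 is >30 days post discharge
        pc.inpatient.append(
            InpatientStay(pid, t0 - timedelta(days=80), t0 - timedelta(days=35), _DX_PNEUMONIA)
        )
        pc.prescriptions.append(
            PrescriptionFill(pid, t0 - timedelta(days=60), "study_psychotropic", "sertraline", 30)
        )

    pc.prescriptions.append(PrescriptionFill(pid, t0, "study_psychotropic", "sertraline", 30))
    ds.sort_claims()
    return ds


# ---------------------------------------------------------------------------
# truth I/O

def write_truth(truth: list[TruthRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [dict(person_id=t.person_id, scenario=t.scenario,
              true_incident_diabetes=str(t.true_incident_diabetes).lower(),
              true_onset_date=t.true_onset_date.isoformat() if t.true_onset_date else "",
              true_subtype=t.true_subtype, detail=t.detail)
         for t in truth],
        columns=["person_id", "scenario", "true_incident_diabetes",
                 "true_onset_date", "true_subtype", "detail"],
    ).to_csv(path, index=False)


def read_truth(path) -> list[TruthRecord]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(TruthRecord(
            str(r.person_id), str(r.scenario),
            str(r.true_incident_diabetes).lower() == "true",
            date.fromisoformat(r.true_onset_date) if str(r.true_onset_date).strip() else None,
            str(r.true_subtype), str(getattr(r, "detail", "")),
        ))
    return out
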