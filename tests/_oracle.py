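"""Brute-force reference adjudicator, written independently of the engine.

Works on day ordinals and flat candidate enumeration: list *every* potential
diabetes-related encounter from every claim, pick the minimum-date candidate
under the evidence-strength tie-break, and adjudicate it by direct scanning.
Used only as a test oracle.
"""

from __future__ import annotations

from datetime import date, timedelta

PREC = {"inpatient_primary": 0, "inpatient_secondary": 1, "outpatient": 2, "prescription": 3}
DIABETES_DRUGS = {"insulin", "insulin_adjunct", "oral_hypoglycemic"}


def _dx_any(codes, match) -> bool:
    return any(match(c) for c in codes)


def _stay_codes(s):
    return (s.primary_dx,) + s.secondary_dx + s.admission_dx


def _visit_codes(v):
    return (v.primary_dx,) + v.secondary_dx


def _pcos_anywhere(pc, lo: date, hi: date, reg) -> bool:
    hits = []
    for v in pc.outpatient:
        hits.append(lo <= v.visit_date <= hi and _dx_any(_visit_codes(v), reg.is_pcos_dx))
    for s in pc.inpatient:
        hits.append(lo <= s.admission_date <= hi and _dx_any(_stay_codes(s), reg.is_pcos_dx))
    return any(hits)


def _stay_t(pc, s, reg, fu_lo: date) -> date:
    prev = s.admission_date - timedelta(days=1)
    ed_dx = any(
        v.visit_date == prev
        and v.setting in ("outpatient", "emergency")
        and _dx_any(_visit_codes(v), reg.is_diabetes_dx)
        for v in pc.outpatient
    )
    if ed_dx and prev >= fu_lo:
        return prev
    return s.admission_date


def oracle_candidates(pc, fu_lo: date, fu_hi: date, reg, pcos_window=120):
    cands = []
    for s in pc.inpatient:
        if fu_lo <= s.admission_date <= fu_hi:
            t = _stay_t(pc, s, reg, fu_lo)
            if reg.is_primary_inpatient_dx(s.primary_dx):
                cands.append(("inpatient_primary", t))
            elif _dx_any(s.secondary_dx + s.admission_dx, reg.is_diabetes_dx):
                cands.append(("inpatient_secondary", t))
    for v in pc.outpatient:
        if v.setting == "physician_inpatient" and reg.is_diabetes_dx(v.primary_dx):
            for s in pc.inpatient:
                if fu_lo <= s.admission_date <= fu_hi and (
                    s.admission_date - timedelta(days=1)
                    <= v.visit_date
                    <= s.discharge_date + timedelta(days=1)
                ):
                    cands.append(("inpatient_secondary", _stay_t(pc, s, reg, fu_lo)))
                    break
    for v in pc.outpatient:
        if v.setting in ("outpatient", "emergency") and fu_lo <= v.visit_date <= fu_hi:
            if reg.is_diabetes_dx(v.primary_dx):
                in_stay = any(
                    s.admission_date - timedelta(days=1)
                    <= v.visit_date
                    <= s.discharge_date + timedelta(days=1)
                    for s in pc.inpatient
                )
                if not in_stay:
                    cands.append(("outpatient", v.visit_date))
    w = timedelta(days=pcos_window)
    for f in pc.prescriptions:
        if f.drug_class in DIABETES_DRUGS and fu_lo <= f.fill_date <= fu_hi:
            if not _pcos_anywhere(pc, f.fill_date - w, f.fill_date + w, reg):
                cands.append(("prescription", f.fill_date))
    return sorted(set(cands), key=lambda c: (c[1], PREC[c[0]]))


def oracle_confirmation(pc, kind: str, t: date, end: date, reg, variant: str) -> str:
    fills = sorted(
        f.fill_date for f in pc.prescriptions
        if f.drug_class in DIABETES_DRUGS and t < f.fill_date <= end
    )
    dx_out = sorted(
        v.visit_date for v in pc.outpatient
        if t < v.visit_date <= end and _dx_any(_visit_codes(v), reg.is_diabetes_dx)
    )
    dx_inp = sorted(
        s.admission_date for s in pc.inpatient
        if t < s.admission_date <= end and _dx_any(_stay_codes(s), reg.is_diabetes_dx)
    )
    if kind == "inpatient_primary":
        return "not_required"
    if kind == "inpatient_secondary":
        if variant == "secondary":
            return "not_required"
        if fills:
            return "by_prescription"
        if dx_out or dx_inp:
            return "by_diagnosis"
        return "none_found"
    if kind == "outpatient":
        if fills:
            return "by_prescription"
        if dx_inp:
            return "by_diagnosis"
        if variant == "secondary" and any(
            t < p.service_date <= end and reg.is_hba1c_proc(p.procedure_code)
            for p in pc.procedures
        ):
            return "by_hba1c_procedure"
        return "none_found"
    if kind == "prescription":
        if dx_out or dx_inp:
            return "by_diagnosis"
        menses = any(
            t < v.visit_date <= end and _dx_any(_visit_codes(v), reg.is_menses_abnormal_dx)
            for v in pc.outpatient
        ) or any(
            t < s.admission_date <= end and _dx_any(_stay_codes(s), reg.is_menses_abnormal_dx)
            for s in pc.inpatient
        )
        has_proc = any(
            t < p.service_date <= end and reg.is_management_proc(p.procedure_code)
            for p in pc.procedures
        )
        if fills and has_proc and not menses:
            return "by_rx_plus_procedure"
        return "none_found"
    raise AssertionError(kind)


def oracle_verdict(pc, fu_lo: date, fu_hi: date, reg, variant: str):
    """(met, encounter_type, initial_index, confirmation/excluded) for the first encounter."""
    cands = oracle_candidates(pc, fu_lo, fu_hi, reg)
    if not cands:
        return (False, None, None, None)
    kind, t = cands[0]
    if kind != "inpatient_primary":
        w = timedelta(days=120)
        if _pcos_anywhere(pc, t - w, t + w, reg):
            return (False, kind, t, "pcos_window")
        conf = oracle_confirmation(pc, kind, t, fu_hi, reg, variant)
        if conf == "none_found":
            return (False, kind, t, "none_found")
        return (True, kind, t, conf)
    return (True, kind, t, "not_required")
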