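"""Validation of a case definition against chart-review adjudication labels.

Positive predictive value (PPV) is the fraction of adjudicated
definition-meeting encounters confirmed as incident diabetes, with Wilson
score intervals.  Because only part of the catchment was adjudicated,
sensitivity and specificity are *design-weighted* estimates: the number of
true cases caught is estimated as (encounters meeting the definition) x PPV,
and the number missed as (encounters not meeting it) x (the adjudicated
true-case proportion among sampled non-meeting encounters),

    sensitivity = a / (a + c),    specificity = d / (b + d),

with b the estimated false positives among meeting encounters and d the
remaining non-cases out of a caller-supplied non-case denominator (the
catchment cohort size is an input, not derived).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .case_definition import CaseRecord

__all__ = [
    "AdjudicationLabel",
    "ValidationCells",
    "UndefinedEstimateError",
    "ppv",
    "wilson_ci",
    "estimate_sensitivity",
    "estimate_specificity",
    "build_validation_cells",
    "contingency_report",
    "validation_metrics",
    "read_adjudication",
    "write_adjudication",
]

ADJUDICATED_STATUSES = (
    "incident_diabetes",
    "prevalent_diabetes",
    "possible_diabetes",
    "subthreshold_hyperglycemia",
    "pcos",
    "lab_rule_out",
    "miscoded",
    "not_diabetes_other",
)
ADJUDICATED_SUBTYPES = ("type1", "type2", "unspecified", "not_applicable")

DEFAULT_Z = 1.959964  # two-sided 95%


class UndefinedEstimateError(ValueError):
    """Raised when an estimator's denominator is empty."""


@dataclass(frozen=True, slots=True)
class AdjudicationLabel:
    person_id: str
    adjudicated_status: str
    adjudicated_subtype: str = "not_applicable"

    def __post_init__(self):
        if self.adjudicated_status not in ADJUDICATED_STATUSES:
            raise ValueError(f"unknown adjudicated_status {self.adjudicated_status!r}")
        if self.adjudicated_subtype not in ADJUDICATED_SUBTYPES:
            raise ValueError(f"unknown adjudicated_subtype {self.adjudicated_subtype!r}")
        incident = self.adjudicated_status == "incident_diabetes"
        if incident != (self.adjudicated_subtype != "not_applicable"):
            raise ValueError(
                "adjudicated_subtype must be set exactly for incident_diabetes labels"
            )


@dataclass(frozen=True, slots=True)
class ValidationCells:
    """Counts feeding the design-weighted sensitivity/specificity estimators."""

    n_meeting: int
    n_meeting_adjudicated: int
    n_meeting_true: int
    n_not_meeting: int
    n_not_meeting_adjudicated: int
    n_not_meeting_true: int
    n_noncases_denominator: int | None = None
    z_quantile: float = DEFAULT_Z

    def __post_init__(self):
        chains = (
            (self.n_meeting_true, self.n_meeting_adjudicated, self.n_meeting),
            (self.n_not_meeting_true, self.n_not_meeting_adjudicated, self.n_not_meeting),
        )
        for true, adj, total in chains:
            if not (0 <= true <= adj <= total):
                raise ValueError("counts must satisfy 0 <= true <= adjudicated <= total")


def ppv(confirmed: int, adjudicated_total: int) -> float:
    """Proportion of adjudicated definition-meeting cases confirmed as true."""
    if adjudicated_total <= 0:
        raise UndefinedEstimateError("PPV undefined with no adjudicated cases")
    if not 0 <= confirmed <= adjudicated_total:
        raise ValueError("confirmed must lie in [0, adjudicated_total]")
    return confirmed / adjudicated_total


def wilson_ci(successes: int, n: int, z: float = DEFAULT_Z) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    center = (p + z^2/2n) / (1 + z^2/n);
    half-width = z/(1 + z^2/n) * sqrt(p(1-p)/n + z^2/(4 n^2)).
    """
    if n <= 0:
        raise UndefinedEstimateError("Wilson interval undefined for n = 0")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if z <= 0:
        raise ValueError("z must be positive")
    p = successes / n
    z2n = z * z / n
    center = (p + z2n / 2.0) / (1.0 + z2n)
    half = (z / (1.0 + z2n)) * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    lo, hi = center - half, center + half
    # the bounds are algebraically exact at the extremes; keep them so
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return max(0.0, lo), min(1.0, hi)


def estimate_sensitivity(cells: ValidationCells) -> float:
    """a/(a+c): caught true cases scaled by PPV vs missed true cases scaled
    by the sampled non-meeting true-case proportion."""
    if cells.n_meeting_adjudicated <= 0 or cells.n_not_meeting_adjudicated <= 0:
        raise UndefinedEstimateError("both adjudicated denominators must be positive")
    a = cells.n_meeting * (cells.n_meeting_true / cells.n_meeting_adjudicated)
    c = cells.n_not_meeting * (cells.n_not_meeting_true / cells.n_not_meeting_adjudicated)
    if a + c == 0:
        raise UndefinedEstimateError("no estimated true cases on either side")
    return a / (a + c)


def estimate_specificity(cells: ValidationCells) -> float:
    """d/(b+d) with b the estimated false positives among meeting encounters
    and d the remainder of the supplied non-case denominator."""
    if cells.n_noncases_denominator is None or cells.n_noncases_denominator <= 0:
        raise UndefinedEstimateError("specificity requires a positive non-case denominator")
    p = ppv(cells.n_meeting_true, cells.n_meeting_adjudicated)
    b = cells.n_meeting * (1.0 - p)
    d = cells.n_noncases_denominator - b
    return d / (b + d)


# ---------------------------------------------------------------------------
# joining engine output with adjudication labels

def _label_map(labels: Iterable[AdjudicationLabel]) -> dict[str, AdjudicationLabel]:
    out: dict[str, AdjudicationLabel] = {}
    for lab in labels:
        if lab.person_id in out:
            raise ValueError(f"duplicate adjudication label for {lab.person_id!r}")
        out[lab.person_id] = lab
    return out


def build_validation_cells(
    cases: Sequence[CaseRecord],
    labels: Sequence[AdjudicationLabel],
    n_noncases_denominator: int | None = None,
    z: float = DEFAULT_Z,
) -> ValidationCells:
    """Assemble the a/b/c/d quantities from engine verdicts and labels.

    Meeting encounters are met case records; non-meeting encounters are
    records with an identified index encounter that failed exclusion or
    confirmation.  Labels join by person id; a label with no matching case
    record raises.
    """
    lm = _label_map(labels)
    ids = {c.person_id for c in cases}
    orphans = sorted(set(lm) - ids)
    if orphans:
        raise ValueError(f"labels without matching case records: {orphans}")

    met = [c for c in cases if c.met_definition]
    unmet = [c for c in cases if not c.met_definition and c.initial_index_date is not None]
    met_adj = [lm[c.person_id] for c in met if c.person_id in lm]
    unmet_adj = [lm[c.person_id] for c in unmet if c.person_id in lm]
    return ValidationCells(
        n_meeting=len(met),
        n_meeting_adjudicated=len(met_adj),
        n_meeting_true=sum(1 for l in met_adj if l.adjudicated_status == "incident_diabetes"),
        n_not_meeting=len(unmet),
        n_not_meeting_adjudicated=len(unmet_adj),
        n_not_meeting_true=sum(1 for l in unmet_adj if l.adjudicated_status == "incident_diabetes"),
        n_noncases_denominator=n_noncases_denominator,
        z_quantile=z,
    )


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (table style)."""
    if denominator == 0:
        return 0.0
    q = Decimal(int(numerator)) * 100 / Decimal(int(denominator))
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_T3_STATUS_ROWS = (
    ("Prevalent diabetes", "prevalent_diabetes"),
    ("Possible diabetes", "possible_diabetes"),
    ("Subthreshold hyperglycemia", "subthreshold_hyperglycemia"),
    ("Polycystic ovarian syndrome", "pcos"),
    ("Laboratory test, rule-out", "lab_rule_out"),
    ("Miscoded diagnosis", "miscoded"),
    ("Other, not diabetes", "not_diabetes_other"),
)


def contingency_report(
    cases: Sequence[CaseRecord],
    labels: Sequence[AdjudicationLabel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulations of adjudication status against the engine's verdicts.

    Returns two frames: adjudication status by computed subtype for meeting
    encounters (any / type 1 / type 2 columns), and adjudication status by
    index encounter type for non-meeting encounters.  Cells hold counts with
    column percentages of the adjudicated total.
    """
    lm = _label_map(labels)
    ids = {c.person_id for c in cases}
    orphans = sorted(set(lm) - ids)
    if orphans:
        raise ValueError(f"labels without matching case records: {orphans}")

    met = [(c, lm[c.person_id]) for c in cases if c.met_definition and c.person_id in lm]
    cols = {"any": met,
            "type1": [(c, l) for c, l in met if c.subtype == "type1"],
            "type2": [(c, l) for c, l in met if c.subtype == "type2"]}

    def cell(n: int, total: int) -> str:
        return f"{n} ({round_pct(n, total):.1f})"

    rows: dict[str, dict[str, str]] = {}
    counts: dict[str, dict[str, int]] = {}
    for col, pairs in cols.items():
        total = len(pairs)
        labs = [l for _, l in pairs]
        inc = [l for l in labs if l.adjudicated_status == "incident_diabetes"]
        col_counts = {
            "Adjudicated: Total": total,
            "Adjudicated: Diabetes": len(inc),
            "Type 1": sum(1 for l in inc if l.adjudicated_subtype == "type1"),
            "Type 2": sum(1 for l in inc if l.adjudicated_subtype == "type2"),
            "Unspecified type": sum(1 for l in inc if l.adjudicated_subtype == "unspecified"),
            "Adjudicated: Not Incident Diabetes": total - len(inc),
        }
        for row_name, status in _T3_STATUS_ROWS:
            col_counts[row_name] = sum(1 for l in labs if l.adjudicated_status == status)
        for row_name, n in col_counts.items():
            denom = total if row_name != "Adjudicated: Total" else total
            rows.setdefault(row_name, {})[col] = (
                f"{n} (100.0)" if row_name == "Adjudicated: Total" and total else cell(n, total)
            )
            counts.setdefault(row_name, {})[col] = n

    meeting = pd.DataFrame(rows).T[["any", "type1", "type2"]] if met else pd.DataFrame()
    meeting.attrs["counts"] = counts

    unmet = [(c, lm[c.person_id]) for c in cases
             if not c.met_definition and c.initial_index_date is not None and c.person_id in lm]
    enc_cols = {"inpatient_secondary": [], "outpatient": [], "prescription": [], "any": unmet}
    for c, l in unmet:
        if c.encounter_type in enc_cols:
            enc_cols[c.encounter_type].append((c, l))

    rows4: dict[str, dict[str, str]] = {}
    counts4: dict[str, dict[str, int]] = {}
    for col, pairs in enc_cols.items():
        total = len(pairs)
        labs = [l for _, l in pairs]
        col_counts = {
            "Adjudicated: Total": total,
            "Adjudicated: Diabetes": sum(1 for l in labs if l.adjudicated_status == "incident_diabetes"),
        }
        col_counts["Adjudicated: Not Diabetes"] = total - col_counts["Adjudicated: Diabetes"]
        for row_name, status in _T3_STATUS_ROWS:
            col_counts[row_name] = sum(1 for l in labs if l.adjudicated_status == status)
        for row_name, n in col_counts.items():
            rows4.setdefault(row_name, {})[col] = cell(n, total) if total else "0 (0.0)"
            counts4.setdefault(row_name, {})[col] = n

    order = ["inpatient_secondary", "outpatient", "prescription", "any"]
    not_meeting = pd.DataFrame(rows4).T[order] if unmet else pd.DataFrame()
    not_meeting.attrs["counts"] = counts4
    return meeting, not_meeting


def validation_metrics(
    cases: Sequence[CaseRecord],
    labels: Sequence[AdjudicationLabel],
    n_noncases_denominator: int | None = None,
    z: float = DEFAULT_Z,
) -> pd.DataFrame:
    """PPV with Wilson CI per subtype stratum, plus the design-weighted
    sensitivity (and specificity when a non-case denominator is supplied).

    The combined type-2-plus-unspecified stratum counts adjudicated type-2
    or unspecified diabetes as confirmation within the computed-type-2
    column, matching how performance for type 2 is customarily summarized.
    """
    lm = _label_map(labels)
    met_adj = [(c, lm[c.person_id]) for c in cases if c.met_definition and c.person_id in lm]

    def stratum(name, pairs, confirm):
        n = len(pairs)
        k = sum(1 for c, l in pairs if confirm(c, l))
        if n == 0:
            return dict(stratum=name, n_confirmed=0, n_adjudicated=0,
                        ppv=float("nan"), ci_low=float("nan"), ci_high=float("nan"))
        lo, hi = wilson_ci(k, n, z)
        return dict(stratum=name, n_confirmed=k, n_adjudicated=n,
                    ppv=ppv(k, n), ci_low=lo, ci_high=hi)

    is_inc = lambda l: l.adjudicated_status == "incident_diabetes"
    t1 = [(c, l) for c, l in met_adj if c.subtype == "type1"]
    t2 = [(c, l) for c, l in met_adj if c.subtype == "type2"]
    out = [
        stratum("overall", met_adj, lambda c, l: is_inc(l)),
        stratum("type1", t1, lambda c, l: is_inc(l) and l.adjudicated_subtype == "type1"),
        stratum("type2", t2, lambda c, l: is_inc(l) and l.adjudicated_subtype == "type2"),
        stratum("type2_plus_unspecified", t2,
                lambda c, l: is_inc(l) and l.adjudicated_subtype in ("type2", "unspecified")),
    ]
    df = pd.DataFrame(out)

    cells = build_validation_cells(cases, labels, n_noncases_denominator, z)
    try:
        df.attrs["sensitivity"] = estimate_sensitivity(cells)
    except UndefinedEstimateError:
        df.attrs["sensitivity"] = float("nan")
    if n_noncases_denominator:
        df.attrs["specificity"] = estimate_specificity(cells)
    df.attrs["cells"] = cells
    return df


# ---------------------------------------------------------------------------
# adjudication label I/O

def read_adjudication(path: str | Path) -> list[AdjudicationLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        AdjudicationLabel(
            str(r.person_id), str(r.adjudicated_status).strip(),
            str(getattr(r, "adjudicated_subtype", "not_applicable")).strip() or "not_applicable",
        )
        for r in df.itertuples(index=False)
    ]


def write_adjudication(labels: Sequence[AdjudicationLabel], path: str | Path) -> None:
    pd.DataFrame(
        [dict(person_id=l.person_id, adjudicated_status=l.adjudicated_status,
              adjudicated_subtype=l.adjudicated_subtype) for l in labels],
        columns=["person_id", "adjudicated_status", "adjudicated_subtype"],
    ).to_csv(path, index=False)
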