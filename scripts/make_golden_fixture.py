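"""Regenerate the packaged person-level validation fixture.

The fixture encodes the published adjudication cross-tabulations as one
case record per catchment encounter (64 meeting the primary definition,
187 not meeting it) and one adjudication label per chart-reviewed person
(46 meeting, 30 sampled non-meeting), so the validation module can
recompute every reported proportion from person-level rows.

Run from the repository root:  python scripts/make_golden_fixture.py
"""

from __future__ import annotations

from datetime import date, timedelta
from pathlib import Path

from phenotyper.case_definition import CaseRecord, write_cases
from phenotyper.validation_stats import AdjudicationLabel, write_adjudication

OUT = Path(__file__).resolve().parents[1] / "src" / "phenotyper" / "data" / "golden"

BASE = date(2000, 6, 15)

# meeting encounters: (computed subtype, adjudicated status, adjudicated subtype, count)
# adjudicated status None means the chart could not be reviewed
MEETING = [
    ("type1", "incident_diabetes", "type1", 12),
    ("type1", "incident_diabetes", "type2", 2),
    ("type1", "prevalent_diabetes", None, 1),
    ("type2", "incident_diabetes", "type1", 1),
    ("type2", "incident_diabetes", "type2", 23),
    ("type2", "incident_diabetes", "unspecified", 3),
    ("type2", "subthreshold_hyperglycemia", None, 3),
    ("type2", "pcos", None, 1),
    ("type1", None, None, 2),
    ("type2", None, None, 16),
]

# non-meeting encounters: (index encounter type, adjudicated status, count)
NOT_MEETING = [
    ("inpatient_secondary", "incident_diabetes", 1),
    ("inpatient_secondary", "possible_diabetes", 1),
    ("inpatient_secondary", "subthreshold_hyperglycemia", 1),
    ("inpatient_secondary", "miscoded", 1),
    ("outpatient", "incident_diabetes", 4),
    ("outpatient", "possible_diabetes", 1),
    ("outpatient", "subthreshold_hyperglycemia", 4),
    ("outpatient", "lab_rule_out", 1),
    ("outpatient", "miscoded", 1),
    ("prescription", "prevalent_diabetes", 1),
    ("prescription", "possible_diabetes", 5),
    ("prescription", "subthreshold_hyperglycemia", 2),
    ("prescription", "pcos", 6),
    ("prescription", "lab_rule_out", 1),
    # the remaining sampled-but-unadjudicated and unsampled encounters,
    # spread over the encounter types the sample exhibited
    ("inpatient_secondary", None, 20),
    ("outpatient", None, 55),
    ("prescription", None, 82),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cases: list[CaseRecord] = []
    labels: list[AdjudicationLabel] = []

    i = 0
    for subtype, status, adj_subtype, count in MEETING:
        for _ in range(count):
            i += 1
            pid = f"M{i:03d}"
            d = BASE + timedelta(days=i)
            cases.append(CaseRecord(
                person_id=pid, met_definition=True, definition_variant="primary",
                initial_index_date=d, final_index_date=d, encounter_type="outpatient",
                confirmation="by_prescription", subtype=subtype,
            ))
            if status is not None:
                labels.append(AdjudicationLabel(pid, status, adj_subtype or "not_applicable"))
    assert i == 64

    j = 0
    for enc_type, status, count in NOT_MEETING:
        for _ in range(count):
            j += 1
            pid = f"N{j:03d}"
            d = BASE + timedelta(days=j)
            cases.append(CaseRecord(
                person_id=pid, met_definition=False, definition_variant="primary",
                initial_index_date=d, encounter_type=enc_type, confirmation="none_found",
            ))
            if status is not None:
                subtype = "unspecified" if status == "incident_diabetes" else "not_applicable"
                labels.append(AdjudicationLabel(pid, status, subtype))
    assert j == 187

    write_cases(cases, OUT / "cases_primary.csv")
    write_adjudication(labels, OUT / "adjudication.csv")
    (OUT / "counts.yaml").write_text(
        "# catchment sampling counts not derivable from person-level rows\n"
        "n_sampled_not_meeting: 113\n"
    )
    print(f"wrote fixture to {OUT}: {len(cases)} cases, {len(labels)} labels")


if __name__ == "__main__":
    main()
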