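# phenotyper

A claims-phenotyping engine for **newly diagnosed (incident) diabetes in
children and youth**, built for pharmacoepidemiologic studies that must
ascertain diabetes onset from administrative health data (enrollment spells,
hospitalizations, outpatient visits, prescription fills, procedure claims)
rather than from laboratory results or chart review.

It is aimed at pharmacoepidemiologists and health-services researchers who
work with Medicaid-style claims extracts and need a validated, configurable,
fully reproducible case definition — plus the statistics to validate one.

## What it implements

**Case definition (rule engine).** Within a new-user cohort's follow-up, the
engine finds *diabetes-related medical care encounters* — hospitalizations
with a primary or secondary diabetes diagnosis (ICD-9-CM family 250),
outpatient visits with a primary diabetes diagnosis, and filled prescriptions
for diabetes medications (insulin, insulin adjuncts, oral hypoglycemics) —
and adjudicates the **first** encounter:

* primary inpatient diagnosis → case met outright;
* any other encounter → excluded if a polycystic-ovarian-syndrome (PCOS)
  diagnosis falls within ±120 days of the index date, otherwise it must be
  **confirmed** by a later claim of a different kind (a diagnosis by a
  prescription; a prescription by a diagnosis, or by a second fill plus a
  diabetes-management procedure with no abnormal-menses diagnosis).

A met case gets a final index date t_x (reset to the earliest
diabetes-related procedure in [t_x−29, t_x−1], the test that triggered the
diagnosis) and a subtype: **type 1** iff an insulin fill occurs in
[t_x, t_x+120] with at most one oral-hypoglycemic fill in that window, else
**type 2**. A *primary* and a relaxed *secondary* variant are provided; the
secondary accepts secondary-inpatient encounters without confirmation and
confirms outpatient diagnoses with a glycosylated-hemoglobin (HbA1c) test
alone, so primary-positive ⊆ secondary-positive.

**Cohort builder.** New-user (recent-initiator) cohort of psychotropic-drug
starters aged 6–24 with one year of baseline enrollment (lapses ≤ 7 days),
baseline medical care utilization, no prior medical care indicating diabetes,
no recent hospitalization (30 days), a 365-day study-drug washout with a
90-day post-discharge allowance, and follow-up censored at study end, the
25th birthday, disenrollment, death, criteria failure, or 365 days after the
last day of current drug use.

**Validation statistics.** Positive predictive value (PPV) against
chart-review adjudication labels with Wilson score intervals,
contingency reports of adjudication status by computed subtype and by index
encounter type, and design-weighted sensitivity/specificity under partial
adjudication:

    sensitivity = a/(a+c),  a = N_meet · PPV,  c = N_miss · p̂_miss
    specificity = d/(b+d),  b = N_meet · (1−PPV),  d = N_noncases − b

where p̂_miss is the adjudicated true-case proportion among sampled
non-meeting encounters and N_noncases is a caller-supplied non-case
denominator.

**Synthetic claims generator.** Seeded, per-person-substream generator of
Medicaid-like claims with planted ground truth covering the full
misclassification taxonomy (canonical type 1/type 2 care streams,
lifestyle-managed diabetes, prevalent disease, PCOS treated with metformin,
single rule-out diagnoses, subthreshold hyperglycemia, miscoded diagnoses,
healthy controls), so the entire pipeline is testable end to end without any
real data.

## Worked example

```bash
phenotyper run-all --seed 1 --n 500 --out demo
```

simulates 500 persons, builds the cohort (481 members; the rest are planted
prevalent-diabetes persons correctly refused at baseline), applies the
primary definition (90 cases met), and validates against the
generator-derived adjudication labels. The report ends with:

```
PPV with 95% Wilson score intervals, by computed subtype stratum:
               stratum  n_confirmed  n_adjudicated  ppv   ci_low  ci_high
               overall           90             90  1.0 0.959064      1.0
                 type1           46             46  1.0 0.922926      1.0
                 type2           44             44  1.0 0.919704      1.0
type2_plus_unspecified           44             44  1.0 0.919704      1.0

Design-weighted sensitivity: 0.8257
```

With noise off every flagged case is a planted true case (PPV = 1.0, the CI
lower bounds reflecting only the finite counts), and the sensitivity below
1.0 is exactly the planted share of medically treated diabetes: the
generator's lifestyle-managed cases are invisible to the primary definition
by design. Individual stages are available as `phenotyper
simulate|cohort|classify|validate`, with code lists supplied as a YAML
registry (`--codes`; defaults ship in the package).

`phenotyper golden-report --out DIR` instead validates against the packaged
person-level fixture encoding a published chart-review validation of this
definition (64 meeting encounters, 46 adjudicated; 187 non-meeting, 30
adjudicated), reproducing its PPV of 89.1% (95% CI 77.0–95.3%) overall,
80.0% for type 1, 83.9% for type 2 plus unspecified, and a design-weighted
sensitivity of 64.7%.

## Layout

| module | role |
| --- | --- |
| `phenotyper.codesets` | code registry (diagnosis/drug/procedure sets) with prefix-matching semantics, YAML-configurable |
| `phenotyper.claims_model` | typed claims tables, CSV readers/writers, enrollment normalization |
| `phenotyper.cohort_builder` | eligibility, qualifying initiation, follow-up windows |
| `phenotyper.case_definition` | the rule engine: encounters, PCOS exclusion, confirmation, index dates, subtype |
| `phenotyper.validation_stats` | PPV, Wilson intervals, contingency reports, design-weighted sensitivity/specificity |
| `phenotyper.synthetic_claims` | seeded scenario generator with planted truth and eligibility probes |
| `phenotyper.cli` | `phenotyper` command group wiring the pipeline |

See `docs/methods.md` for the underlying model, parameter defaults, and
known limitations.
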