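# Methods

## Problem and approach

Administrative claims record diagnoses, prescription fills and procedures,
not disease. A computable case definition for incident diabetes in children
and youth must therefore separate true new-onset disease from the main
sources of misclassification in this age group: diagnostic work-ups that end
in a single rule-out code, subthreshold hyperglycemia, prevalent disease
carried into the cohort, miscoded hospital diagnoses, and — specific to
populations with many reproductive-age women — polycystic ovarian syndrome
(PCOS), which is routinely treated with the same oral hypoglycemics used for
type 2 diabetes. The engine implements a confirmation-based rule set over
four encounter pathways, plus the statistics needed to validate any such
definition against chart-review labels, and a synthetic claims generator
that plants each of those misclassification mechanisms as an explicit
scenario.

All dates are whole calendar days; every interval written [a, b] is closed
on both ends. The gap between enrollment spells ending day e and starting
day s is s − e − 1 days, so abutting spells have zero gap.

## Code matching

Diagnosis codes are normalized to decimal-free ICD-9-CM strings ("250.13" →
"25013") and matched by prefix at the three-digit family boundary or deeper.
One refinement keeps enumerated code lists faithful: when a set contains a
pattern **and** one of its proper extensions (the diabetes
primary-inpatient list contains "250" alongside "2500"…"2509"), the shorter
pattern matches exactly only — the list is read as enumerating the
subcategories it intends, which is how a published list of the form
"250, 250.0, 250.1, 250.2, 250.3, 250.9" excludes the complication
subcategories 250.4x–250.8x. A consequence is that the
"match of a union = union of matches" identity holds only for pattern sets
that do not refine one another; the property test is scoped accordingly.

Every code list is data, not code (`data/codesets_default.yaml`), because
the clinically named sets ("procedure indicating diabetes management",
"absent/irregular menses") have no canonical published code list. Defaults:
HbA1c 83036; management/index-reset procedures additionally 82947, 82950,
82951 (quantitative glucose and tolerance testing); menses families 626.0,
626.1, 626.4; PCOS 256.4. Drug classification comes from an explicit
`drug_class` column (insulin | insulin_adjunct | oral_hypoglycemic |
study_psychotropic | other) rather than an NDC dictionary, which is
site-specific.

## Cohort

Entry (time zero) is the first study-drug (psychotropic) fill on a day
satisfying every criterion: age 6–24 (completed years; the upper bound is
the day before the 25th birthday); normalized enrollment covering the
preceding 365 days, tolerating lapses ≤ 7 days; at least one claim of any
type in that year (the weakest defensible reading of "medical care
utilization"); no diabetes diagnosis or diabetes-medication fill at any
earlier time; no exclusion condition (life-threatening illness,
institutional residence, schizophrenia/psychosis, pregnancy, PCOS) active on
the day — consumed as a pre-computed flag table because no code lists exist
for them here; and no hospital discharge in the preceding 30 days nor a stay
in progress.

Washout: no study-drug fill in [F−365, F−1], with the allowance that fills
confined to [F−90, F−1] do not disqualify F provided the earliest fill of
that cluster has its own clean 365-day washout (patients restarting therapy
shortly after a hospital discharge). The no-recent-hospitalization rule and
the post-discharge allowance are in tension for restarts within 30 days of
discharge; both are applied as stated, so the allowance in practice admits
restarts 31–90 days after discharge.

Follow-up runs from the day after the qualifying fill to the earliest of:
study end (default 1996-01-01–2007-12-31), day before the 25th birthday,
end of the enrollment spell containing entry, death, the start of an
exclusion flag, or 365 days after the last day of current use. Current use
is a fill chain: each study-drug fill covers `days_supplied` days (default
30 when the column is absent, grace period 0), and a fill extends the chain
only if it occurs before coverage lapses.

## Case definition

Encounter extraction emits, for events inside follow-up:

* **inpatient-primary** — stay whose primary discharge diagnosis is in the
  restricted diabetes list; index date = admission date, moved to the prior
  day when an ED/outpatient visit with a diabetes diagnosis fell on that day
  (only if that day is still inside follow-up, keeping index dates within
  the observation window);
* **inpatient-secondary** — stay with a secondary or admission diabetes
  diagnosis, or a professional claim (`setting=physician_inpatient`) with a
  primary diabetes diagnosis dated within a stay period (day before
  admission through day after discharge); index date as above;
* **outpatient** — outpatient/ED visit with a primary diabetes diagnosis not
  inside any hospital stay period (such visits are attributed to the
  hospitalization); professional inpatient claims that match no stay are
  ignored rather than treated as outpatient visits;
* **prescription** — diabetes-medication fill with no PCOS diagnosis in
  [fill−120, fill+120].

Ties on the index date resolve by evidence strength (inpatient-primary >
inpatient-secondary > outpatient > prescription). Only the **first**
encounter is adjudicated; if it is PCOS-excluded or unconfirmed the member
is not a case (`fall_through=True` exposes the alternative reading that
later encounters may be tried, default off).

Confirmation searches (initial index date, follow-up end]; a claim on the
same calendar day as the encounter never confirms it (bundled same-visit
claims must not self-confirm), except that the management procedure of the
prescription pathway may share a date with the confirming second fill. A
`confirmation_window_days` config can cap the search window; the default is
uncapped within follow-up, the weakest reading of "subsequent". The
secondary variant is the primary variant's rules plus relaxations only
(secondary-inpatient auto-confirm; outpatient confirmable by HbA1c alone),
which guarantees the primary-positive ⊆ secondary-positive property the
engine's tests assert.

Index reset takes the **earliest** qualifying procedure in [t_x−29, t_x−1]
(the test initiates the clinical episode). The subtype window is one-sided,
[final index, final index+120]: the index is by construction the first
diabetes-related event, so a two-sided window would be vacuous to the left
except after an index reset, which the window still covers. Insulin
adjuncts (pramlintide) do not count toward the type-1 insulin requirement
(configurable).

## Validation statistics

`wilson_ci(k, n, z)` uses the score interval
(p̂ + z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n), z defaulting to
1.959964 (two-sided 95%); bounds are pinned to exactly 0 and 1 at k = 0 and
k = n where the algebra demands it. The tests cross-check against
statsmodels' implementation to 10⁻¹² on a grid.

Sensitivity and specificity are design-weighted estimates for a partially
adjudicated catchment, a/(a+c) and d/(b+d) with a = N_meet·PPV,
c = N_miss·p̂_miss, b = N_meet·(1−PPV), d = N_noncases − b. The non-case
denominator is an input, never derived: the catchment cohort size needed to
compute it is not recoverable from person-level validation rows. When every
encounter is adjudicated the sensitivity estimator reduces algebraically to
the true-positive fraction, which the tests assert exactly on synthetic
data. Applied to the packaged fixture's counts (64 meeting, 41/46 true;
187 non-meeting, 5/30 true) the estimator gives 0.6467 (64.7%); published
reports of this design quote 64.8%, a 0.1-point difference attributable to
rounding or a denominator detail in unpublished supplementary arithmetic —
the package implements the stated formula and documents, rather than
patches, the divergence. No confidence interval is attached to the
sensitivity estimate because its two-stage sampling design does not admit a
simple binomial interval. Report percentages round half-up to one decimal,
matching standard table style.

The packaged fixture (`data/golden/`) is a **synthetic person-level
reconstruction** of a published validation cross-tabulation: one case record
per catchment encounter and one label per adjudicated person, with the
unadjudicated remainder's encounter types spread plausibly (only the
adjudicated cells and the margins are determined by the source counts). The
113-of-187 sampled count cannot be derived from person rows and ships as a
sidecar `counts.yaml`.

## Synthetic data

Every person receives an enrollment spell covering [t0−380…480, t0+800], a
baseline utilization visit, and ten 28-day psychotropic fills from t0, so
all scenario events (onset t0+30…150, confirmations within ~60 further
days) fall safely inside follow-up even for members censored at the 25th
birthday. Ages are uniform over [6, 24) years at entry; sex is female with
probability 0.77 (echoing the heavily female composition of psychotropic-
treated Medicaid cohorts); scenario mixes default to a catchment-like
composition in which most diabetes-related encounters are not true incident
cases (46% healthy, 18% canonical type 1/type 2, 5% lifestyle-managed, and
5–8% each of the false-positive mechanisms).

Scenario semantics (noise off): canonical type 1 → inpatient-primary or
outpatient diagnosis followed by insulin fills; canonical type 2 →
outpatient diagnosis, metformin fills, HbA1c, occasionally a pre-diagnosis
glucose test that exercises the index reset; lifestyle-only type 2 →
diagnosis + HbA1c, no fills (caught only by the secondary variant);
PCOS-metformin → fills with a PCOS diagnosis within ±90 days, never caught;
rule-out and subthreshold → a single diagnosis (± glucose test), never
confirmed; miscoded → an isolated secondary inpatient diagnosis, a false
positive of the secondary variant only; prevalent → diabetes care before t0,
refused at baseline, unless `leak_prevalent` suppresses the pre-entry claims
to model disease visible only to chart review (the prevalent false-positive
mechanism). Visit gaps are geometric (mean 30 days, capped at 60);
`confirm_drop_prob` (default 0) deletes confirming claims to create false
negatives.

Randomness is one substream per person keyed by (seed, person index), so
changing the population size or adding scenarios never perturbs earlier
persons — generator output is byte-stable under config evolution, and the
tests assert it.

What the generator does **not** emulate: real coding noise (miscodes beyond
the planted scenario), laboratory values (adjudication thresholds exist only
as truth labels), billing detail, provider effects, informative censoring,
or correlated comorbidity. Passing tests therefore demonstrate that the
engine implements the stated rules exactly and that the estimators recover
planted parameters under the stated sampling design — not that the
definition's published operating characteristics transfer to any particular
real population.

## Problem sizes in the test suite

The property suite runs the full pipeline on 100 seeded datasets of 500
persons (variant-ordering), 200 replicates of 1,000 persons
(parameter recovery within 3 Monte-Carlo standard errors), 2×200 random
small persons against a brute-force oracle, and exact boundary probes for
every window ([t_x±120] PCOS, [t_x−29, t_x−1] reset, stay periods, the
≤1-oral-fill subtype rule). These sizes give Monte-Carlo standard errors
well below the asserted tolerances while keeping a full run in the
low tens of seconds.

## Known limitations

* Exclusion conditions are consumed as flags, not derived from codes.
* The secondary variant's published validation counts are not encoded in
  the fixture (its supplementary tables print no cell counts); it is
  exercised against synthetic truth instead.
* ICD-10 translation, X12/837 parsing and OMOP mapping are out of scope.
* The chart-review process itself (adjudication criteria, inter-rater
  resolution) is represented only as ground-truth labels.
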