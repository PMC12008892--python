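# Methods

## Design

`hcvddi` implements a descriptive new-user cohort design on
administrative-claims-shaped tables.  There is no outcome model and no
inferential statistics: the estimands are counts and proportions of
patients exposed to interacting comedications during DAA treatment,
overall, by regimen, and within comorbidity / HCV-severity strata.

### Study constants (`StudyConfig`)

| parameter | default | unit | role |
|---|---|---|---|
| study period | 2017-01-01 … 2023-08-31 | dates | all records must fall inside |
| identification period | 2017-04-01 … 2023-08-31 | dates | window for index events |
| `gap_threshold_days` | 7 | days | refill gap ending an episode |
| `lookback_months` | 3 | calendar months | required pre-index enrollment; also the baseline comedication window (Japan allows at most 3 months of supply per prescription, so 3 months of data suffice to see every active drug) |
| `transplant_window_days` | 90 | days | transplant exclusion window, inclusive at both ends |
| `min_age_years` | 18 | years | completed-years age at index |
| `hcv_icd10` | B18.2 | code | qualifying HCV diagnosis |
| `daa_regimens` | SOF/VEL = J05AP55, GLE/PIB = J05AP57 | ATC | exposure definition |
| transplant codes | K697-5/6/7 | procedure codes | liver-transplant records |

### Cohort rules and their edge cases

* **Index date** — earliest DAA prescription inside the identification
  period; all regimens prescribed on that exact date form
  `regimens_on_index`.  One index event per patient; later re-initiations
  are not separate entries.
* **Age** — completed years by birthday arithmetic, not calendar-year
  subtraction.
* **Look-back** — enrollment must cover, as one continuous (merged,
  adjacent-day) span, every day from the first day of the third calendar
  month before the index month through the index date itself.  Requiring
  enrollment on the index date is a design choice here (the selection rule
  is meaningless for a patient not observable at index).
* **Transplant window** — `[index − 90 d, index]`, both ends inclusive; a
  procedure 91 days before index does not exclude.
* Rules apply in a fixed order (age, HCV diagnosis, look-back, multiple
  DAA, transplant); each patient is removed at the first failing rule, so
  attrition counts are additive and conserve the initial total.

### Treatment episodes and follow-up

A prescription starting day *d* with supply *s* covers *d … d+s−1*.  The
episode walk extends while `next_date − episode_end < 7` days, where
`episode_end` is the running maximum covered day; overlapping refills take
the max of ends (no stockpiling) while `treatment_days` stays the plain sum
of supplies.  Follow-up ends at the earliest of episode end
(discontinuation), first other-regimen DAA prescription strictly after
index (switch), end of the merged enrollment span containing the index
date (disenrollment), or the study end.  Date ties resolve
switch > disenrollment > discontinuation > study end.  A consequence of
this tie-break worth knowing: if enrollment in the data ends exactly on the
study end date, the label is `disenrollment`; the generator therefore
extends non-disenrolled patients' enrollment past the study end, as real
insurance enrollment would.  A different-regimen prescription censors
follow-up but does not retroactively truncate `episode_end` or
`treatment_days`.

### DDI classification

The knowledge base stores, per (regimen, ingredient), the package-insert
status (`none`/`caution`/`contraindicated`) and the Liverpool checker
status (`not_listed`/`no_interaction`/`yellow`/`amber`/`red`).

* `is_ddi` = Liverpool colour present **or** PI flag present (union rule).
* severity = Liverpool colour if present; otherwise PI mapping
  (contraindicated → Red, caution → Amber).  An explicit
  `no_interaction` listing combined with a PI flag is still a DDI and takes
  the PI severity — one consistent reading of an under-specified corner,
  fixed here and tested via an exhaustive 15-cell truth table.
* `is_potential` = Liverpool colour present and PI silent.
* A patient's severity is the maximum over comedications
  (none < Yellow < Amber < Red), making the severity table a partition of
  each group.

Comedications are ingredients with ≥ 1 prescription dated in the closed
interval `[index, followup_end]`, excluding the index regimen's own ATC
code; the *other* DAA regimen counts as a comedication (and is Red against
GLE/PIB).  Supplies overlapping into follow-up from pre-index prescriptions
are not counted — a deliberate mirror of the data-source convention this
design emulates, and a known source of underestimation.  Matching is exact
on normalized (lower-case, slash-joined combination) ingredient strings; no
ATC-hierarchy inference, for determinism and auditability.

The bundled `kb.csv` covers the full GLE/PIB contraindicated list
(including entries expected to tally zero), the antipsychotic,
gastrointestinal and lipid-lowering classes for both regimens, and the
individually named Red drugs.  Per-row source attribution (which of the two
knowledge sources flags the drug) is best-effort where public labels are
ambiguous; the resulting severity grade is the tested quantity.  SOF/VEL
has no Red entry.

### Covariates

Comorbidity flags use the Quan ICD-10 adaptation of the Charlson index
(prefix matching after stripping dots; unmapped codes ignored), with the
original weights 1/2/3/6 and hierarchy rules (complicated diabetes ≻
uncomplicated; moderate/severe liver ≻ mild; metastatic ≻ any malignancy).
The baseline window is every diagnosis dated in or before the index month —
the design leaves this open, so it is a configuration of the mapping stage,
and on generated data it coincides with "enrollment start through index
month".  The baseline comedication count is the number of distinct non-DAA
ingredients prescribed in the 3 calendar months strictly before the index
month.  HCV severity is graded decompensation codes (K72, I85, R18, …) >
cirrhosis codes (K74, K70.3) > B18.2 > others; because a cohort patient by
definition has B18.2 in the index month, `others` is unreachable for
included patients (see below).

### Formatting

Percentages: `100·n/denominator` with decimal half-up rounding to one
decimal, denominator = group (or stratum) total.  Continuous summaries:
mean with sample SD (n−1; blank for n = 1) and median with IQR = Q3 − Q1
under linear-interpolation (type-7) quantiles — the convention is not
dictated by the design, so the numpy default is used and stated here.

## The synthetic-claims generator

The generator (`hcvddi.simulate`) draws each patient once and emits both
the claims rows and the truth labels from the same draws, so truth and data
cannot disagree by construction.  Defaults encode the study conditions:

* group assignment P(SOF/VEL) = 467/7338 ≈ 0.064;
* truncated-normal ages floored to whole years, SOF/VEL 73.8 (SD 10.5),
  GLE/PIB 69.7 (SD 13.3), bounds 18–100;
* per-group comorbidity prevalences matching the published baseline table
  (independent Bernoulli draws; no correlation structure);
* HCV severity mix SOF/VEL 27.6 % decompensated / 2.1 % compensated /
  70.3 % chronic and GLE/PIB 0.3 / 3.3 / 96.4 %.  The published table also
  lists an "others" share (17.3 / 13.3 %), but under this package's
  severity precedence a cohort patient always classifies at least as
  chronic hepatitis C, so that share cannot be planted without breaking
  exact truth recovery; it is folded into the chronic category and the
  config validator rejects a positive `others` probability as infeasible.
  Likewise "moderate or severe liver disease" is not an independent dial:
  it emerges from the decompensated draw (code K72.9 maps to both), since
  an independent draw could silently reclassify a planted chronic patient.
* per-drug comedication probabilities calibrated to the published per-drug
  follow-up shares (e.g. esomeprazole 0.165 against SOF/VEL, lansoprazole
  0.0738 against GLE/PIB), plus a pool of non-interacting common drugs;
  draws are independent per drug, so the implied any-DDI prevalence is
  `1 − Π(1 − p_d)` over interacting drugs — about 44 % for SOF/VEL and
  34 % for GLE/PIB.  The published prevalences (59.3 / 51.5 %) are higher
  because the real data include a long tail of additional interacting
  drugs (a supplementary list not transcribed here) and correlated use;
  recovery tests therefore compare against the *configured* prevalence,
  not the published one, and condition on patients without a realized
  regimen switch (the switch prescription adds the other DAA as a
  comedication through a separate mechanism, `p_switch`).
* treatment durations 12/24 weeks (0.9/0.1) for SOF/VEL and 8/12 weeks
  (0.6/0.4) for GLE/PIB, realized as back-to-back 28-day refills; with
  probability `p_gap_event` (0.10) one refill boundary is stretched to a
  gap of 7–21 days, exercising the episode-breaking branch; refills dated
  past the study end are dropped (administrative censoring);
* `p_switch` = 0.02, `p_disenroll_during_treatment` = 0.03;
* planted ineligibility: 2 % under-age, 3 % HCV diagnosis in the wrong
  month, 3 % short look-back, 1 % dual regimen at index, 1 % recent
  transplant — each a minimal single-rule violation so the attrition flow
  is checkable one rule at a time.

What the generator does **not** emulate: correlated comorbidity structure,
dose/route information, realistic fee-schedule billing, insurance-switch
identity fragmentation, and the long tail of interacting drugs outside the
bundled knowledge base.  Passing recovery tests therefore demonstrates that
the pipeline implements its stated contract exactly — not that the
synthetic prevalences equal those of any real population.

## Numerical and degenerate-input choices

* Calendar arithmetic is exact (`datetime.date`); months are `YYYY-MM`
  strings; no timezone handling.
* `severity_max` of an empty set is `none`; an empty knowledge base is
  valid; an empty bundle round-trips as six header-only files.
* Facility attribution on same-day index prescriptions at multiple
  facilities: lexicographically smallest facility id, for determinism.
* All generator randomness flows through one `numpy` Generator seeded from
  the config; equal seeds give byte-identical CSV output.

## Problem sizes

Test and acceptance runs use populations of 250–2,500 patients (2,000 for
the recovery suite, five seeds), 5,000 random refill sequences for the
episode oracle and 200 random mini-bundles for the cohort oracle — sizes at
which every binomial recovery check has adequate width while the full suite
stays fast on one CPU.

## Known limitations

* Only DAA–comedication pairs are assessed; comedication–comedication
  interactions are out of scope.
* Drugs started before the index and merely continued (supply overlapping
  into follow-up) are invisible to the comedication window.
* The bundled knowledge base is a curated subset, not the full checker; a
  study against real data should supply its own `kb.csv`.
* ICD-10 codes are not validated against the official classification, and
  diagnosis records carry no "suspected" flag.
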