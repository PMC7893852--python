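# frailscan

Frailty case definitions over linked primary-care EMR and administrative
health data.

Frailty — the clinical syndrome of reduced strength, endurance and
physiological reserve in older adults — has no biomedical marker, so
population-level identification must be squeezed out of routinely collected
data. `frailscan` implements, end to end, the analysis pattern used to
study this problem in linked provincial data: two independent case
definitions (one over primary-care EMR events, one over administrative
claims), a deterministic person-level linkage between the sources, cohort
inclusion rules, rolling-window chronic-condition classification, and
descriptive comparison of the mutually exclusive groups the two definitions
produce. Because the real linked data are confidential, the package ships a
first-class synthetic-data generator: a latent Clinical-Frailty-Scale-like
score (1 = very fit … 9 = terminally ill, frail ⇔ score ≥ 5) drives code
emission, primary-care contact volume, institutionalization, costs and
next-year mortality, so every stage is testable against known truth.

It is written for epidemiologists and health-services researchers who work
with EHR phenotyping: the library is the primary interface, a thin
`frailscan` CLI covers shell use, and `examples/` walks through each
capability.

## The definitions

**EMR definition** — a boolean rule over code atoms evaluated on a 6-year
lookback: dementia diagnosis (ICD-9 290), prescriptions for vitamins and/or
furosemide (ATC A11, C03CA01), and "obstruction" as a whole-token free-text
keyword. The shipped rule is
`dementia OR (vitamins AND furosemide) OR obstruction`, stored in an
editable JSON rule file (`src/frailscan/data/emr_definition.json`); the
published definition names these ingredients but not its exact boolean
structure, so the expression is an explicit reconstruction.

**Administrative definition** — frail if at least one of three index-year
rules fires: (1) residence in long-term care or assisted living; (2)
terminal-illness coding (defaults ICD-9 V66.7, ICD-10-CA Z51.5); (3) at
least two *distinct* claims-detectable domains of the modified Edmonton
Frail Scale (cognition, mood, incontinence, falls/mobility, nutrition,
functional dependence, social support, polypharmacy >5 distinct
medications). Domain code sets ship as editable YAML.

**Learned definitions** — a CHAID (Chi-square Automatic Interaction
Detection) learner over binary code-presence atoms: category groups are
merged by pairwise chi-square, splits selected by Bonferroni-adjusted
p-values (multiplier = Stirling number S(c, r)), complexity chosen by
out-of-bag bootstrap misclassification, and operating characteristics
(sensitivity, specificity, PPV, NPV with exact Clopper–Pearson 95% CIs)
estimated by stratified 10-fold cross-validation.

## Worked example

```python
from frailscan import (SimConfig, generate, link_deterministic, build_cohort,
                       apply_emr_definition, apply_admin_definition,
                       default_definition, assign_groups)

emr, admin, truth = generate(SimConfig(n_persons=5000, seed=7))
xw = link_deterministic(emr, admin)          # exact match on PHN
cohort = build_cohort(emr, admin, xw, index_year=2014)
emr_calls = apply_emr_definition(default_definition(), emr, cohort, 2014)
admin_calls = apply_admin_definition(admin, cohort, 2014)
groups = assign_groups(emr_calls, admin_calls, cohort)
print(groups.groupby("group").size())
```

prints

```
admin_only     485
both           471
emr_only       547
neither       3150
```

— the four mutually exclusive groups among the 4,653 included persons: 547
flagged only by the EMR rule (community-dwelling, earlier on the frailty
continuum), 485 only by the administrative rules (institutionalized or
terminally ill, largely invisible to primary-care records), 471 by both, and
the rest by neither. `examples/05_descriptive_tables.py` continues this run
into the characteristic/utilization tables and the chi-square / Welch-t
group comparison; `examples/06_learn_definition_chaid.py` shows the CHAID
learner recovering a planted two-atom rule exactly
(`['and', 'dementia', 'furosemide']`, holdout accuracy 0.980).

## Data formats

Each source is a directory of six CSVs (`persons.csv`, `claims.csv`,
`hospitals.csv`, `prescriptions.csv`, `ltc.csv`, `observations.csv`),
ISO-8601 dates, UTF-8, LF endings; writing is canonical so read→write round
trips are byte-identical. One example row each:

| table | example row |
|---|---|
| persons | `E0000001,900001234,1941-03-12,female,,3,V6T2B5,2009-01-01/2015-12-31` |
| claims | `E0000001,2014-02-07,290.0,,gp,48.21` |
| hospitals | `A0000001,2015-03-02,2015-03-11,J18.9,10421.55` |
| prescriptions | `E0000001,2014-05-19,C03CA01,emr,23.4` |
| ltc | `A0000001,2013-11-02,,long_term_care` |
| observations | `E0000001,2014-06-30,systolic_bp,128.0` |

(`coverage_episodes` packs closed date intervals as `start/end;start/end`;
`icd10_codes` joins multiple diagnoses with `;`.)

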