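# Methods

## The measurement problem

Frailty is operationalized here as a latent ordinal severity scale from 1
(very fit) to 9 (terminally ill), with the frail state defined as a score of
5 or more. Neither primary-care EMR data nor administrative claims observe
this scale; each source observes correlated traces (diagnosis codes,
prescriptions, institutionalization, utilization). The package's job is to
(a) evaluate fixed, auditable case definitions over those traces, (b) learn
definitions from labelled reference data, and (c) characterize who each
definition captures — all on synthetic data whose generating truth is known.

## Synthetic linked population

`simulate.generate` draws one population and splits it into an EMR view and
an administrative view.

**Latent model.** Age at Jan 1 of the index year is 65 + Exp(mean 8 years),
truncated at 105; 55% of persons are female. The latent score comes from an
ordered logistic model: a linear predictor of +0.6 per decade over 65 and
+0.3 for women, plus standard logistic noise, cut at eight fixed thresholds.
The model's intercept is solved numerically (Brent's method on the exact
expected fraction) so that P(score ≥ 5) matches `frail_fraction_target`
(default 0.15, in the range implied by published frail-group counts). An
unreachable target raises `CalibrationError` rather than silently drifting.

**Emission model.** Every observable "atom" — dementia coding, furosemide,
vitamins, "obstruction" free text, LTC entry, terminal-illness coding, each
of seven coded Edmonton-Frail-Scale domains, and eight chronic conditions —
fires as a Bernoulli event with one probability for frail persons and one
for non-frail (`emission_probabilities`). Defaults were picked once as
plausible for a 65+ primary-care population (e.g. hypertension 0.80/0.55,
dementia coding 0.30/0.03); they are conditions of the simulation, not
tuning knobs. Routine GP contacts use innocuous ICD-9 codes disjoint from
every rule's code family so contact volume cannot leak into classification.

**Quantitative anchors.** GP contacts per year are negative binomial with
means 20 (frail) and 10 (non-frail) — the published ~2:1 contact ratio —
and dispersion 1.5. Hospital admissions are Poisson (0.5 vs 0.15 per year)
with gamma lengths of stay (means 12 vs 6 days); costs are gamma
distributed around class means; distinct-medication counts are Poisson
(7 vs 3.5), which drives the >5-medications polypharmacy flag. Death in the
year after the index year is logistic in the latent score,
expit(−7.5 + 0.9·score): ≈1% at score 3, ≈5% at 5, ≈25% at 7 — echoing the
reported death rates of frail groups while keeping monotonicity in the
latent scale, the only property tests rely on. A fraction of persons dies
within the index year itself (0.6× the next-year probability), exercising
the utilization denominators.

**Linkage structure.** Each EMR person appears in the administrative source
with probability 1 − `unlinked_fraction` (default 0.03, emulating the
97%/96% deterministic linkage rates of the two provinces the design
mirrors), and an equal-sized block of admin-only persons is added. All event
dates are clamped at death.

**Planted rules.** `plant_rule` rewrites the emission probabilities of a
chosen atom conjunction so frail persons satisfy the whole conjunction with
probability p₁ and non-frail with p₀ (each atom at the k-th root). Atoms
whose code family collides with another emitter (dementia coding vs the
dementia chronic condition) silence the collider, otherwise the stated
operating probabilities would be inflated by leakage. Recovery tests plant
at 0.95/0.01; note that at the commonly quoted 0.9/0.05 the *Bayes-optimal*
holdout accuracy at a 15% frail fraction is only ≈0.94, so demanding >0.95
requires the cleaner plant, not a better learner.

**What the generator does not emulate.** Real coding-frequency
distributions beyond the rule-relevant atoms; provider- and region-level
clustering; migration; miscoding and transcription noise; any real fee
schedule (costs are simulated aggregates); associations between frailty and
income/rurality are absent (no published joint distribution is strong
enough to calibrate one). Passing tests therefore demonstrate correctness
of the *machinery* under a known truth, not real-world operating
characteristics of the definitions.

## Linkage and scrambling

Linkage is exact match on personal health number, nothing else: the link
set is the PHN intersection, duplicates within a source are an error (the
deterministic rule is undefined), and there is no probabilistic fallback.
The linkage rate's denominator is the EMR person count by default (the
study cohort is drawn from EMR patients); the admin denominator is an
option since the published convention is not stated. `scramble_ids`
emulates the trusted-third-party step: person ids become a keyed SHA-256 of
the PHN, the keymap is returned separately, and released bundles carry no
PHN column.

## Cohort inclusion

Included: linked ∧ aged 65+ in completed years on Jan 1 ∧ ≥1 EMR GP
encounter in the two calendar years ending with the index year ∧ registry
coverage on ≥75% of the days alive in the index year. The exclusion label
is the first failing rule in that order; because the rules are a pure
conjunction, order affects labels only, never membership (tested).
Coverage uses actual calendar day counts on merged closed intervals (leap
years fall out naturally); exactly 75% is retained, matching a strict
"<75% excluded" reading. Specialist-only contact does not satisfy the
visit rule. A person dead before the index year has coverage 0 and a flag.

## EMR rule engine

Atoms are ICD-9 prefixes (dot-insensitive), ATC prefixes, or free-text
keywords; keyword matching is whole-token and case-insensitive, so
"obstruction" does not fire on "obstructive". Expressions are nested
AND/OR/NOT trees over named atoms, validated at construction, evaluated
per person over the window [Jan 1 of index_year − lookback + 1, Dec 31 of
index_year] (default lookback 6 years: primary-care records need longer to
surface frailty criteria than index-year administrative data). Every frail
call carries an evidence trail of (atom, date, code-or-text). For
negation-free expressions the engine is monotone in added events; engine
output equals brute-force truth-table evaluation (property-tested over
random expressions on ≤10 atoms).

## Administrative rules

Rule 1 fires on ≥1 day of overlap between any LTC/assisted-living episode
(open-ended episodes included) and the index year. Rule 2 fires on any
palliative/terminal code in the index year; the default set (V66.7, Z51.5)
stands in for unpublished provincial criterion lists and is fully
overridable, as is everything in `admin_rules.yaml`. Rule 3 counts
*distinct* Edmonton-Frail-Scale domains with index-year evidence —
duplicated events never change the count — with the polypharmacy domain
defined as more than 5 distinct full ATC codes in the year; the default
threshold of 2 domains is configurable.

## Rolling-window comorbidity

A condition is present given ≥1 hospital diagnosis matching its ICD-10-CA
prefixes or two physician claims matching its ICD-9 prefixes within a
rolling window, interpreted as "any two qualifying claims ≤730 days apart"
(365 for depression); the calendar-anniversary alternative was rejected as
leap-year-dependent without material difference. Same-day claim pairs
count (flagged as a sensitivity-analysis point). Depression additionally
lapses unless the index year contains treatment evidence — an
antidepressant (ATC N06A), a depression claim, or a depression
hospitalization — whenever the first qualification predates the index
year. The sorted-dates implementation is equivalent to the O(n²) all-pairs
check because a within-window pair exists iff an adjacent sorted pair is
within the window (property-tested against the brute force). Counts are
computed separately per source and banded 0-1 / 2 / 3+.

## Descriptive tables and tests

Cohort members are partitioned into four exclusive groups (EMR-only,
admin-only, both, neither; the published analysis reports the three frail
groups, `neither` completes the partition invariant). Characteristics use
index-year data: age bands 65-74/75-84/85+, sex, income dichotomized high
(quintiles 3-5) vs low (1-2), rural = '0' as the second character of the
postal forward sortation area (applied uniformly; the
statistical-area-classification variant used in one province needs an
external lookup and is out of scope), and blood pressure/BMI as the mean of
the up-to-3 most recent readings in the two-year characteristics window
(date ties resolved by stable input order). Utilization, costs,
polypharmacy and death use the year after the index year, with persons who
died during the index year excluded from denominators; hospitalizations are
reported per 100 persons; hospital days count the closed admit-discharge
interval. Costs map GP fees → GP care, specialist fees → specialist care,
hospital abstract costs → acute hospital care, dispensation costs →
prescriptions; a separate laboratory/imaging category is not representable
in the claim schema and is omitted. All table numbers are rounded to one
decimal, half away from zero. Group comparisons use Pearson chi-square
without continuity correction and the Welch (unequal-variance) t-test —
the plain "t-test"/"chi-square" of the source convention, with the safer
variance assumption — flagged at 0.05 / 0.01 / 0.0001; degenerate inputs
(zero margins, zero variance) report p = 1 with a warning instead of NaN.

## CHAID learner

At each node, for each feature: categories start as singletons and the pair
of groups with the largest pairwise chi-square p is merged while that p
exceeds `alpha_merge` (or until two groups remain). The split p-value on
the merged table is Bonferroni-multiplied by the number of ways the c
observed categories can collapse into the r merged groups — the Stirling
number S(c, r), the classical multiplier for free (nominal) predictors.
The node splits on the smallest adjusted p ≤ `alpha_split` provided every
child reaches `min_node_size` and depth < `max_depth`. Chi-square tests
are Pearson, uncorrected, with zero-margin degeneracy mapping to p = 1.
Tie-breaks are deterministic: categories and groups are kept sorted, and
feature evaluation order is column order.

Complexity selection averages out-of-bag misclassification over shared
bootstrap resamples (paired comparison across candidates); exact ties go to
the smaller depth, then the larger minimum node size — simpler trees win.
Cross-validation uses seeded stratified folds (round-robin within class
after a shuffle) and pools all out-of-fold predictions into a single
confusion matrix before computing metrics, so small folds never produce
unstable per-fold ratios. Sensitivity, specificity, PPV and NPV carry
exact Clopper–Pearson 95% intervals (beta quantiles); an empty prediction
margin makes PPV/NPV undefined-with-warning rather than 0/0. For binary
presence features the fitted tree converts back into the same JSON rule
form the EMR engine consumes (`tree_to_expression`): positive leaves become
AND-paths, OR-ed together.

One arithmetic note: a published PPV of 53% is not consistent with
sensitivity 28% and specificity 94% on a 875-person reference set with 150
frail (those imply PPV ≈ 49%); the package always reports metrics computed
from its own confusion matrices.

## Pipeline and determinism

`run_pipeline` executes simulate → link → cohort → classify → comorbidity →
summarize from one config, writing plain CSV/JSON artifacts plus a manifest
with the seed, per-stage row counts and a hash of the analysis-relevant
configuration. Every random draw descends from the single seed through one
`numpy` generator, and all writes are canonical (sorted, fixed column
order, LF), so two runs with one seed are byte-identical — verified at the
byte level in the test suite.

## Problem sizes

Unit and property tests run at n ≤ 1,500 persons; calibration checks use
n = 20,000 (binomial error ≈ 0.3% on the frail fraction), planted-rule
recovery n = 10,000 with a 30% holdout, and determinism n = 5,000 — sizes
at which the Monte-Carlo tolerances quoted in the tests (±0.02 on the frail
fraction, ±1.5% on the linkage rate, [1.8, 2.2] on the contact ratio) have
comfortable margins.

## Known limitations

The default code lists (conditions, EFS domains, terminal illness) are
documented stand-ins for validated but unpublished sets — results on real
data depend on replacing them. The EMR definition's boolean structure is a
reconstruction from its published ingredients. Free-text handling is
whole-token keyword matching only; no NLP. The generator's independence
assumptions (atoms conditionally independent given the latent class) make
recovery problems easier than real phenotyping, which is exactly why the
package reports operating characteristics from data rather than asserting
them.
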