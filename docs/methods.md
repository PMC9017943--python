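# Methods

This note documents the data model, the cleaning and inference rules, the
synthetic cohort generator, the audit statistics, and the design choices
made where the problem was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

An extract is one flat table, one row per injectable-drug administration,
in UTF-8 comma-delimited text with ISO-8601 dates and empty cells for
missing values. Center category and region travel denormalized on each row,
as real pharmacy exports do; the centers table is rebuilt at load time. The
extraction date lives in a JSON sidecar (`<file>.meta.json`) and defaults to
the latest administration date. The full column dictionary ships as
`eprkit/data/data_dictionary.csv`.

Loading is conservative and accounted: every input row becomes either a
record or a fatal row error (`rows_in = records + fatal_rows`, asserted).
Rows without a parseable administration date or without center/patient
identifiers are fatal, because every downstream rule orders records per
patient by date; any other unparseable or out-of-domain cell (e.g. a
negative dose) is set to missing and reported as a field-level error while
the row is kept.

Controlled vocabularies are package conventions, since pharmacy systems do
not share one coding scheme: disease stage is `early < locally_advanced <
metastatic` (ordered by severity), diagnosis is `breast_cancer |
lung_cancer | other`, response is `CR | PR | SD | PD`. Same-day ties are
broken deterministically (date, INN lexical, cycle number, input order) so
all rules are reproducible.

## Standardization

Free text is mapped by exact lookup after normalization (lowercase,
diacritics stripped, whitespace collapsed) against plain-CSV synonym tables
(French and English seeds shipped; editable without code changes). Drug
names resolve through a brand→INN map plus an alias table for spelling
variants; the match status distinguishes `matched` (brand evidence agrees),
`inn_only`, `brand_conflict` (brand maps to a *different* INN — the trigger
for exclusion rule R2) and `unknown_drug`. No fuzzy matching: unknowns are
surfaced in the codification report rather than silently miscoded, and no
record is ever dropped at this stage. Codification is idempotent because
every canonical code is its own synonym.

The shipped brand map and other-cancer drug list are synthetic seed data —
small, plausible formularies sufficient for the synthetic cohorts — not an
authoritative clinical reference; a deployment would replace them with its
own validated catalog files.

## Exclusion rules

A patient is removed if any of five record patterns makes their history
unreliable: R1 truncated start (smallest observed cycle number in the
earliest regimen episode > 1 — typically an EPR software migration; if no
cycle number is recorded there, truncation cannot be asserted and the
patient is kept), R2 brand/INN mismatch, R3 same INN twice on one calendar
day, R4 two or more distinct recorded primary diagnoses, R5 any
administration of a drug on the other-cancer exclusion list. Rules are
evaluated in listing order and each patient is counted once, under the
first rule triggered, so the flow chart's per-rule counts are disjoint and
conserve the extracted population per cancer and overall — an invariant
asserted at run time and in tests.

A *regimen episode* — the unit for R1 and for the inference rules — is a
maximal run of administration days with an identical INN set and no
treatment-free gap above `gap_days` (default 60: one cycle length of slack
over typical 14–28-day cycles).

## Stage and line inference

Stage rules, in order: **S1** copies a missing stage from the nearest
originally-recorded stage in the same episode (backward first, then
forward; only original values serve as sources, so the result does not
depend on fill order). **S2** derives a still-missing stage from the
regimen label through a keyword table (longest keyword wins; "néoadjuvant"
therefore beats its substring "adjuvant"). **S3** enforces that disease
severity never regresses: a recorded stage strictly below the running
maximum is raised to it. Patients with any stage still missing are removed
under R6; consequently R6 counts *still-missing* stages only — conflicting
stages are always corrected by the ratchet rather than grounds for
exclusion.

Line rules run after stage resolution because numbering restarts when the
patient enters the metastatic phase (standard oncology convention; records
are partitioned into a pre-metastatic and a metastatic phase). **L1** fills
a missing line from the episode's first recorded line. **L2** numbers
episodes 1, 2, … within a phase when the phase has no recorded line at all;
as a documented generalisation, an unlined episode inside a *partially*
lined phase continues from the previous episode's line + 1 — without this,
the contract that retained patients reach 100% line completion would be
unreachable for histories whose gaps do not span a whole phase, and R6 (by
design) only removes stage-unresolved patients. **L3** forces lines
non-decreasing within a phase.

This rule set is one concrete, auditable instantiation of a three-step
framework (retrieve from other entries, check consistency over time, derive
from treatment features). Each rule carries a stable identifier
(`S1_fill_within_regimen`, …) and every modified value produces exactly one
audit entry (patient, record, rule, field, before, after), so individual
rules can be replaced by site-specific ones without touching the QC
machinery. Inference is idempotent: a second pass produces zero changes
(tested), and after inference stage severity is non-decreasing and lines
are positive, phase-monotone integers for every retained patient.

## Assessment

Completion rates are computed per variable on the analyzable population:
patient-level variables (demographics, diagnosis, stage, line, drivers,
response, …) count a patient as complete if *any* of their records carries
a value; record-level variables (drug, dose, date, cycle, …) count records.
Variables below 70% completion are flagged not usable and no imputation is
attempted. Coverage divides cohort patient counts by national counts from a
hospital-activity reference, per (cancer × category/region) stratum and in
total, each patient counted once at the center of their first
administration; a coverage of one third of nationally treated patients is
the conventional sufficiency anchor. Representativeness compares cohort and
national patient shares per stratum: absolute differences in percentage
points, a flag above `flag_threshold_pp`, and a chi-square goodness-of-fit
of cohort counts against the national share vector (scipy), reported
descriptively — it never gates a run, and no multiplicity correction is
applied.

`flag_threshold_pp` defaults to 4.0, calibrated so that category gaps of
the size historically judged discrepant in national benchmarks (about 4–7
points, typically university hospitals and one under-represented region)
flag while 3-point gaps do not. Display rounding is half away from zero —
integer percent for coverage and lung-cancer shares, one decimal for
breast-cancer shares, matching the precision of the published benchmark
table — while reports always carry full precision underneath.

## Quality control

For each inference rule, the patients it touched form the population N; a
simple random sample is reviewed and the correct-application proportion is
estimated with the exact Clopper–Pearson interval (Beta quantiles,
`scipy.stats.beta.ppf`; cross-checked in tests against statsmodels'
`proportion_confint(method="beta")`). The sample size is the
finite-population-corrected

    n = ceil( n0 / (1 + n0/N) ),   n0 = z² p (1−p) / e²

with defaults e = 0.10 (margin of error), z = 1.65, p = 0.50 (worst-case
variance), giving n0 = 68.0625 ≈ 68 and about 60 reviewed patients for
populations of a few hundred. Ceiling rounding is the conservative reading
of "approximately 60". When a rule touched no more patients than the
uncorrected planning size (69 at the defaults), every patient is reviewed
instead of sampling — the behaviour a human chart review would adopt.

Correctness of a sampled patient means: for every field a rule changed on
that patient, the *final* inferred value equals the ground truth. The final
value is judged (not the rule's intermediate output) because a later rule
may legitimately finish a correction an earlier fill started. In a
production deployment the reference is a human chart review; here it is the
synthetic generator's retained truth — the sampling and estimation
machinery is identical by design.

## Synthetic cohorts

The generator emulates the structure of pooled EPR extracts at the study
conditions the pipeline is built for. Each patient receives 1–4 sequential
regimens drawn from cancer-specific pools (every combination contains a
cohort-defining drug of interest; consecutive regimens differ in
composition), given every 14–28 days for 3–8 cycles; a stage trajectory
(early-only, early→metastatic, locally-advanced→metastatic, or
metastatic-only) assigns each regimen a stage and a within-phase line
number, which are recorded as truth before any corruption. Free text is
emitted with realistic dialect noise: case variants, French/English
synonyms, brand names in the drug field.

Defaults are fixed at the emulated program's published completion profile
and flow-chart scale and are not tuning knobs: patient-level stage masking
0.07 (BC) / 0.23 (LC) and line masking 0.20 / 0.30 (the complements of the
93%/77% and 80%/70% pre-completion rates); truncation 0.037 (the truncated
share of the published flow chart) and the four other error causes at 5–6
per mille each (the remaining excluded share split about equally, since no
per-rule prevalences are published — they are free parameters); cancer mix
0.835 breast; 12 centers × 50 patients by default. Masked patients are
recoverable by construction — stage from regimen-label keywords, lines from
regimen structure — except for a 5% `uninformative_label_rate` whose labels
carry no stage keyword, populating R6. Small record-level nuisance rates
(isolated stage/line dropouts 3%/5%, spurious stage regressions 2%,
conflicting line entries 2%) exercise the fill and correction rules without
moving patient-level completion, so completion-based recovery of the
masking rates stays exact. Injected errors are mutually exclusive per
patient by default (per-rule counts are then unambiguous and the engine's
sensitivity is testable as exactly 1); a flag allows overlaps for testing
rule precedence. One `numpy.random.Generator` drives everything: a fixed
seed reproduces the extract byte for byte.

The national reference implied by a configuration is deterministic: each
stratum's configured cohort count scaled by an inflation factor (> 1,
default 3), preserving the distribution shape, so coverage against a
generated extract is ≈ 1/inflation everywhere.

What the generator does *not* model — and hence what passing tests do not
establish about real extracts: survival, toxicity and dosing pharmacology;
oral and out-of-hospital treatments (a real cause of missing sequences);
patients moving between centers (no cross-center linkage exists); regimen
labels that are genuinely wrong rather than missing; correlated missingness
(all draws are independent); and vendor-specific layout quirks beyond
vocabulary drift. Quality-control proportions of 1.0 on synthetic cohorts
certify the machinery, not the clinical accuracy of any rule on real data,
where only chart review can do so.

## Numerical and scale choices

Problem sizes in the test suite are chosen for tight statistical bounds at
desk scale: rate-realization and recovery checks use 5,000-patient cohorts
against exact binomial 99% intervals; interval-coverage checks use 2,000
simulated review replicates at n = 60 and true proportions 0.5/0.9/0.97;
conservation is checked over 1,000 small randomized extracts with rates
drawn across their ranges. The session-wide example cohort is 600 patients.
Degenerate inputs are defined, not errors: an empty file is an empty
extract; an empty analyzable population skips assessment with an explicit
warning; a rule that touched no patients yields an empty QC result; a
stratum with cohort patients but no national count reports undefined
coverage with a warning; `p = 0` gives a review sample of zero. Percentage
display uses half-away-from-zero rounding throughout.

## Known limitations

Stage and line inference is deliberately conservative and rule-based; it
cannot recover a stage for which no same-episode record, no informative
label and no later consistency signal exists, and it will faithfully
propagate a *consistently* wrong recorded stage (the ratchet corrects
regressions, not elevations). The severity ratchet assumes disease stage is
monotone within one primary cancer — true by construction here, an
approximation clinically. Exclusion sensitivity of 1.0 holds on synthetic
data because injected violations are unambiguous by construction; real
extracts contain borderline patterns (e.g. legitimate same-day split doses)
that the rules would count as violations. The composite patient key
(center, patient) cannot link one person treated in two centers.
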