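# Methods

This note records the modelling conventions, parameter choices and known
limitations behind `oncogtt`. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Screening model

A trigger is a pure predicate over a single admission; the engine emits
at most one hit per (trigger, admission), dated at the earliest
qualifying evidence. Per-admission counting is the unit of account
throughout: the reference totals this package replays (1,556 positives
over 500 records across 37 triggers) are per-record counts, and the PPV
denominator is positive *triggers*, not positive measurements.

Conventions where the rule text leaves room:

- **Strict comparisons.** All numeric cutoffs use strict `<` / `>`
  exactly as written; a value exactly at a cutoff never fires. The
  synthetic generator places hit-inducing values 10% beyond the cutoff
  (or mid-grade-band for the graded cytopenias) precisely so that a
  boundary-strictness bug cannot hide.
- **ULN/LLN resolution.** Ratio rules (hepatotoxicity L5, creatinine L6)
  use the lab row's own reference range, falling back to the analyte
  vocabulary default. Units are canonical per analyte; readers reject
  rather than convert.
- **L5.** ALT or direct bilirubin above 2×ULN; or AST, ALP and total
  bilirubin all above their ULN *on the same collection date* with at
  least one above 2×ULN ("simultaneously" = same date).
- **L6.** Creatinine above 1.5×ULN, or above 1.5× the admission baseline
  (earliest creatinine; flagged pre-admission baselines within 30 days
  sort first), or GFR below 60; the "and/or" is implemented as OR.
- **L7.** A reading above 140/90 (SBP > 140 OR DBP > 90) counts only if an
  earlier in-admission reading was fully normal (SBP ≤ 140 AND DBP ≤ 90).
  SBP/DBP rows sharing a timestamp form one reading.
- **L8/L9.** Vetoed by the `diabetes-mellitus` comorbidity term.
- **L16 and L22.** The comma in "CK-MB > 25 U/L, CK > 200 U/L" is read as
  a conjunction, as is the morning ACTH + cortisol pair in L22 (secondary
  adrenal insufficiency requires both low); L22 additionally enforces the
  stated 7–10 am / 6–10 am collection windows.
- **S1/S3 attributes.** Symptom predicates that need a numeric attribute
  (temperature, stools/day) log a warning and do not fire when it is
  missing. S3 fires on >4 stools/day OR diarrhea plus a companion code
  (bellyache, hemoproctia, mucous stool, fever), mirroring the "and/or"
  phrasing.
- **T1.** "Simultaneous" glucocorticoid + antihistamine = order date
  spans overlapping on ≥1 calendar day (window configurable).
- **T3.** Leucovorin orders are ignored for colorectal and gastric
  tumors, where the drug is part of standard regimens.
- **M2.** Only therapy adjustments flagged as toxicity-motivated count;
  planned titrations do not.

Inclusion: malignancy diagnosis, age ≥ 18, antineoplastic exposure, and
length of stay in [2, 30] days. The lower bound is inclusive by default
(the reference cohort's own stay range starts at 2 days); a strict
"longer than 2 days" reading is available via `strict_los=True`.

## Adjudication

Trigger hits are clues; reviewers assert the event. A reviewer
annotation per (admission, trigger) supplies the ADE term, causality
answers, suspected drugs, seriousness flags and — outside the
auto-graded analytes — the CTCAE grade.

- **Causality** follows the Karch–Lasagna categories via an explicit
  ordered decision table (shipped as data, amendable per site): no
  temporal relation ⇒ doubtful; unknown reaction pattern ⇒ conditional
  (doubtful when an alternative explanation exists); alternative
  explanation ⇒ possible; dechallenge improvement with rechallenge
  recurrence ⇒ certain; dechallenge improvement alone ⇒ probable;
  otherwise possible. The table is total over all 72 answer
  combinations; combinations the original prose leaves open (e.g.
  rechallenge positive without dechallenge) resolve to the most
  conservative matching row. Only certain/probable/possible events are
  counted downstream.
- **Severity.** CTCAE v5.0 value bands auto-grade the four cytopenias
  (HGB, WBC, NEUT, PLT) from the hit's laboratory evidence, overriding
  the annotation; grading is monotone in the value and returns nothing
  within normal limits. All other terms take the reviewer grade.
- **Deduplication.** Candidates on the same admission with the same ADE
  term and onsets within 7 days of the cluster anchor are one event; the
  merged record unions triggers, drugs and SAE criteria, keeps the
  earliest onset and the worst grade. Candidates are canonically sorted
  first, so the operation is order-insensitive and idempotent. The 7-day
  same-term window is a declared convention (configurable); it
  reproduces multi-trigger merging without collapsing distinct episodes.
- **Seriousness** is criteria-list-only: an event is an SAE iff at least
  one regulatory criterion (hospitalization, disability, congenital
  anomaly, intervention required, life-threatening, death, other
  serious) is flagged; grade is deliberately not used.

## Metrics

γ, per-trigger/overall PPV and the three detection rates are ratio
computations; display follows the reference table's convention (one
decimal below 10%, integer percent otherwise; γ and rates to one
decimal). PPV for a zero-positive trigger is reported as a flagged 0.0.

The 95% CIs for the two ADE rates offer two constructions — normal
approximation on per-admission counts (point ± 1.96·SD/√N, scaled to the
denominator) and Poisson (point ± 1.96·√count, scaled). The construction
behind externally printed intervals for such rates is typically
unstated; neither method claims to match any particular published
interval, and the tests assert only the properties that identify a sane
interval: it contains the point estimate and tightens as √n.

The risk-factor analysis is the conventional two-stage recipe:
univariate χ² (categorical) and two-sample t (continuous) screens with
raw P < 0.05 entry (no multiplicity correction, matching field
practice), then a maximum-likelihood logistic model (statsmodels) with
Wald 95% CIs on the odds ratios. Complete separation is flagged per
variable, never silently estimated. Published odds ratios cannot be
reproduced without the underlying patient-level data; the substitute
evidence is frequentist calibration — on simulated cohorts with planted
ORs of 2.0 and 0.5 (n = 5,000 per replicate), the 95% Wald intervals
must cover the truth in ≥93% of replicates. The test suite uses 600
replicates so that Monte-Carlo noise in the observed coverage (SE ≈0.9%)
cannot flip the verdict; the acceptance script reports 200-replicate
coverage values.

## Synthetic cohorts

`SynthConfig` defaults are the reference study's conditions: 500
admissions; per-trigger positivity = positives/500 and linkage = the
per-trigger PPV; demographics from the published characteristics table;
causality mixture 180:492:8; severity mixtures per ADE term from the
published severity table; suspected-drug weights from the 45-drug,
1,032-mention catalogue. Length of stay is a rounded log-normal matched
to mean 6.53 / SD 4.21 days, truncated to [2, 28] — the distribution
family is a convention, the source reports only moments and range.
Covariates the study does not tabulate (prior chemotherapy count,
prior-ADR history, radiotherapy) use fixed realistic rates (Poisson(2),
20%, 15%).

Triggers are drawn independently across triggers and admissions — the
source gives no joint distribution. Two consequences worth knowing:
(1) generated γ runs a few points above a clustered real cohort's, since
independence spreads hits across more admissions; (2) predicate
exclusions (diabetes for L8/L9, colorectal/gastric for T3) condition the
draw, slightly deflating those triggers' effective positivity. Non-hit
admissions carry a normal-value panel strictly inside reference ranges.
Ground truth (which hits carry ADEs, with term, grade, causality, drugs)
is emitted as a separate annotations file so screening cannot see labels.
What passing generator tests show is calibration against the *configured*
probabilities under these assumptions — not clinical realism: there is no
pharmacokinetics, no care-pathway structure, no trigger–demographic
correlation.

## Replay fixture

`build_replay_fixture()` is RNG-free. Allocation: ADE-bearing hits of
the 34 term-bearing triggers round-robin over admissions 0–314 with
per-term grade sequences matching the severity table; the antidote/
intervention triggers T3, M1 and M2 — whose linked events are ADEs
already identified by a laboratory or symptom trigger — attach to the
first ADE of 35 distinct admissions, which is the only realization
consistent with both the per-trigger link counts and the unique-ADE
table (35 = 715 − 680 = 2 + 1 + 32); the remaining 841 non-ADE hits
round-robin over admissions 0–458; admissions 459–499 stay
trigger-negative. Causality and the 1,032 suspected-drug mentions are
interleaved proportionally over the 680 events; all grade-4 events are
flagged life-threatening and grade-3 events add prolonged
hospitalization until exactly 77 admissions are serious. Stays of 6 or
7 days are spread to total 3,264 patient-days. Demographic assignment
respects the predicate exclusions (no diabetes on glucose-trigger
admissions, no colorectal/gastric tumors on leucovorin-trigger
admissions). A self-check runs the full real pipeline and verifies every
marginal family — per-trigger positives and links, hit/ADE admission
counts, unique events and merges, per-term severity, causality,
seriousness, drug mentions, patient-days — before the fixture is
returned.

## Problem sizes and runtime

The default test run builds the 500-admission fixture once per session,
screens generated cohorts of 20–800 admissions for property tests, uses
24 seeds × 250 admissions for the binomial-sampling check and 600
replicates × n = 5,000 for OR-coverage; the whole suite runs in well
under a minute on one CPU, and the acceptance script in a few seconds.

## Known limitations

- Coded inputs only: no free-text/NLP extraction, no HL7/FHIR ingestion,
  no unit conversion (producers must emit canonical units).
- The built-in organ-class vocabulary is a simplified MedDRA-like map;
  suspected-drug attribution is reviewer-supplied, never inferred from
  timing.
- The two rate-CI constructions are documented choices, not a claim
  about any particular published interval.
- Generator realism ends at the configured marginals; see above.
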