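# Methods

This note documents the engine's model, the content choices behind the
shipped rule registry, the synthetic population, and the numerical
conventions, so that results are interpretable and the configurable pieces
are visible.

## The pipeline

One evaluation run has five components, executed in order and logged by
name: **collect** (parse and validate the clinical extract; administer the
12-item HRA), **integrate** (reconcile extract and HRA into a profile with
per-field provenance), **interpret** (classify lab values and vitals
against patient-specific goals; compute the coronary risk score),
**recommend** (evaluate all 18 service rules, classify statuses, assemble
the summary page), and **act** (detailed messages, clinician summary,
discrepancy flags, reminders).

## Patient data and the merge policy

The clinical extract is a minimum dataset: demographics, blood pressure,
height/weight, lipid panel, glucose or A1c, PSA, immunization and
screening dates with structured result flags, medications, and problem-list
conditions. Dates are ISO-8601; units are canonical (mg/dL, mmHg, cm, kg, %,
ng/mL) and non-canonical units are rejected rather than converted — unit
conversion is a reader concern, and silent conversion would make rule
evaluation depend on upstream formatting.

The HRA has 3 behavior items (tobacco use, physical activity, diet
quality) and 9 history/demographic items (race/ethnicity; family history of
colorectal cancer plus an age-at-diagnosis band; family history of
breast/ovarian cancer, of premature coronary disease, and other; prior
abnormal pap, mammogram, and colonoscopy/sigmoidoscopy). The exact item
wording and answer scales of a deployed questionnaire are not public; the
shipped identifiers and scales are placeholders, marked configurable, that
cover the domains the rules consume. The behavior/history split (3 + 9) is
fixed; the allocation of the nine history items across domains is a package
convention.

Merge authority is asymmetric: patients are authoritative for HRA-domain
facts (behaviors, race/ethnicity, family history, prior abnormal results —
things EMRs record poorly or as uninterpretable narrative), the EMR for
labs, vitals, and service dates. A declined answer leaves the field
`absent`, which can only surface as `missing_info` — the engine never
imputes. Pap, mammogram, and colonoscopy results flagged `text_only` are
routed to the patient questionnaire by the completeness report. A prior
HRA never auto-fills the new one; old answers appear as confirm-only
prompts (staleness window default 12 months).

Age is completed years; a Feb-29 birthday rolls to Feb 28 in non-leap
years.

## The rule registry

The registry is a versioned YAML document; the engine is table-driven and
guideline-agnostic, so swapping the file swaps the clinical content. The
shipped content encodes USPSTF A/B recommendations of the 2007–2010
generation plus the bodies USPSTF defers to (JNC VII, NCEP ATP III, ADA,
ACIP, Healthy People, Dietary Guidelines): 4 cancer-screening services, 5
heart-care, 5 health-behavior, 3 vaccines, 1 other — 18 in all. Windows
and intervals are the package's transcription of those guidelines (e.g.
colorectal screening 50–75 every 10 years by colonoscopy, start age 40
with a first-degree relative diagnosed before 60; mammography 40–74 every
2 years; AAA ultrasound once for men 65–75 who ever smoked).

Three mechanisms personalize beyond age/sex: **risk modifiers** (predicates
that override window or interval), **indication gates** (service indicated
only when a gate predicate holds — tobacco counseling for current smokers,
diabetes screening for elevated blood pressure), and **uncertainty flags**
for shared-decision services. Uncertainty defaults to prostate-cancer
screening (all eligible men) and the mammography start-age stratum (40–49),
the two canonical examples; both services' messages carry a risks block and
a how-to-decide block. Organization variants attach to a rule for
discrepancy detection; the shipped pair is diabetes screening, where USPSTF
(screen with elevated blood pressure) and ADA (screen at 45, or younger
with BMI >= 25) can disagree. A flag is emitted only when both variants are
decidable and differ.

When a predicate needs an absent field, the engine enumerates the possible
values; only if the verdict actually depends on the answer does it return
`insufficient_info` (naming the field). This keeps the invariant that
missing information is reported exactly when it is decisive.

Due dates are calendar-month arithmetic (`most recent qualifying event +
interval`, day clamped to month end), because intervals are stated in
months and years; the shift-invariance of due dates therefore holds at
month, not day, granularity. No prior event means due immediately; a
completed one-time service never recurs; the most recent qualifying event
governs. There is no grace period (a service is overdue the day it is
due); both the convention and the 90-day reminder suppression window are
configurable.

## Interpretation and risk scoring

Goals are patient-specific. LDL follows the ATP III strata: < 100 mg/dL
with coronary disease or a risk equivalent (diabetes, peripheral arterial
disease, stroke), < 130 with two or more major risk factors (smoking,
hypertension, HDL < 40, age — men 45 / women 55, family history of
premature coronary disease), otherwise < 160. Unknown risk factors count
as absent, the conservative choice for goal selection. Blood pressure
follows JNC VII (< 140/90; < 130/80 with diabetes). HDL is protective and
flagged only when low. Analytes without an encoded rule come back
`not_interpretable` rather than being compared to a generic range.

The ten-year coronary-risk calculator is the NCEP ATP III Framingham
point-score system, chosen because ATP III is the registry's cholesterol
authority. The sex-specific published tables are encoded verbatim; the
open-ended bins are represented numerically ("<1%" as 0.5, ">=30%" as
30.0) so the score is always a percentage. Smoking status comes from the
patient's own behavior answer, treated blood pressure from the medication
list. One property of the published tables worth knowing: because the
cholesterol and smoking points attenuate with age band while age points
rise, the total is *not* globally monotone in age (a 49-year-old male
smoker with TC >= 280 outscores his 50-year-old self by 2 points); the
tables are kept faithful rather than smoothed, and monotonicity holds in
systolic pressure, total cholesterol, and (inversely) HDL everywhere.

## Messages and actionability

Status classification is a total mapping: `insufficient_info ->
missing_info`, `not_indicated -> not_indicated`, `uncertain -> discussion`,
indicated and due on or before the evaluation date -> `due_now`, otherwise
`up_to_date`; each state has a fixed cue token (action/ok/info/na/unknown)
so renderers can style without clinical logic. The summary page's
"needs now" section is exactly the due-now services plus chronic values
above their patient-specific goal — the same computation feeds the
clinician summary's overdue-care section, so the two views cannot diverge.

Every detailed message carries five domains (patient summary, condition
information, benefits, next steps, guidance resources) and satisfies six
data-level actionability features: explicit next steps; at least one
personalization token interpolated from the profile; a non-empty benefits
block; resources attached exactly when their predicates match (ordered
decision aid, risk calculator, self-management, community resource,
logistics — the ordering is a package convention); prior values trended
whenever any exist; and a closing link back to the patient's own
clinician. Template prose is neutral placeholder wording with
interpolation slots, intended to be replaced by professionally written
patient-education copy; the lay dictionary and the sig grammar
(count + PO + QD/BID/TID/QID) translate clinical shorthand, and anything
unrecognized passes through unchanged rather than being guessed at.

## Longitudinal behavior

Re-evaluation appends to a strictly date-increasing per-patient log and
reports the status delta. Reminders fire only on transitions *into*
due-now and are additionally guarded by the suppression window, so the
reminder count for a service never exceeds its transitions into due-now,
re-running on unchanged state is a no-op, and a service completed and due
again a full interval later reminds again. Payloads carry only the lay
service name and a link token — no clinical values in email. Replaying the
same timeline reproduces the identical log and reminder stream.

## Synthetic population

The generator emulates the engine's eligible frame: adults 18–75 with an
office visit in a 6-month observation window. Per-patient draws come from
a dedicated `(seed, index)` stream, so records are reproducible
individually and under parallel generation. Defaults are round numbers for
a generic adult panel — condition prevalences (hypertension 0.30,
hyperlipidemia 0.25, diabetes 0.10, coronary disease 0.07), behavior mixes
(20% current smokers), 60% prior-screening probability with recency spread
over 1.5 intervals, 3% declined answers, and narrative-text results for
pap/mammogram/colonoscopy with probability 1.0 (matching how those reports
reach EMRs). Account creation is Bernoulli per visitor at uptake 0.144 with
return-visit probabilities 0.49 (0–3 months) and 0.10 (3–6 months).
Multi-practice simulation spaces 14 per-practice uptake probabilities
evenly across a configurable [0.015, 0.283] range — a deterministic grid
rather than random draws, so the simulated spread brackets the configured
heterogeneity without extra variance.

What the generator does *not* emulate: correlated comorbidity structure,
within-patient longitudinal lab drift, visit-frequency heterogeneity, and
any mechanism for *why* uptake varies across practices. Passing tests
therefore demonstrate engine correctness and statistical calibration of
the generator's marginals, not fidelity to any real practice population.

## Problem sizes and tolerances

The test suite checks rule-engine/oracle equivalence on ~10,400 profiles
(both sexes × ages 18–75 × 90 risk-factor combinations sampled from the
full factor space), reminder discipline over 10-year simulated timelines
re-evaluated quarterly, prevalence recovery at n = 1,000–1,200 within 3
binomial SD, and the adoption simulation at the full 50,124-visitor scale
(binomial draws are vectorized, so this is cheap). Statistical assertions
all use 3-SD bands; exact assertions (counts, worked arithmetic, string
translations) have no tolerance. Uptake percentages are half-up rounded to
one decimal, computed in decimal arithmetic to avoid float rounding
surprises at the .x5 boundary.

## Known limitations

- Guideline content is a snapshot; the registry is versioned precisely so
  content updates are data changes, not code changes.
- The colorectal rule uses one 10-year interval for all modalities rather
  than modality-specific intervals (FOBT annually, sigmoidoscopy 5-yearly).
- Blood-pressure "treatment" for risk scoring is inferred from a fixed
  antihypertensive name list; unlisted drugs read as untreated.
- The HRA item wording and the message prose are placeholders, and the
  resource catalog is illustrative.
- No HL7/CCD/FHIR parsing, no free-text NLP, no transport (email/EMR
  write-back are modeled as serialized artifacts only).
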