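# precare

Guideline-driven preventive-care decision support for adult primary care.

`precare` re-implements the computational core of an interactive preventive
health record: it merges a patient's EMR clinical extract with a short
patient-completed health risk assessment (HRA), evaluates a declarative
registry of **18 preventive services** (cancer screening, heart care, health
behaviors, vaccines, and other services), and produces

- a per-service status — `due_now`, `up_to_date`, `discussion`,
  `not_indicated`, or `missing_info` — with a visual cue token,
- a five-section **general summary page**: what the patient needs now,
  dates services were last received, prior test values, category overviews,
  and missing information,
- a five-domain **detailed personal message** per service (patient summary,
  condition information, benefits, next steps, guidance resources), with a
  risks block and a how-to-decide block for shared-decision services,
- a three-section **clinician summary** (updates/corrections, health
  behaviors, overdue care), and
- a longitudinal loop that re-evaluates on a schedule and emits
  suppression-window-guarded **patient reminders**.

It is written for clinical-informatics researchers and tool builders who
need a deterministic, auditable, guideline-agnostic rules engine with a
fully synthetic test population — no patient data required anywhere.

## The model in brief

Eligibility is table-driven. A service rule is
`(applicable sex, age window [a_min, a_max], recurrence interval m,
risk modifiers, indication gate, uncertainty flag)`; modifiers are
predicates over the merged profile that override the window or interval
(e.g. a first-degree relative with colorectal cancer diagnosed before 60
lowers the colorectal start age from 50 to 40), and the gate makes services
like tobacco-cessation counseling conditional on a patient answer. A
service is *due* when `last qualifying event + m months <= as_of` (never
screened means due immediately; completed one-time services never recur).
When a verdict depends on an answer the patient declined, the engine
reports `insufficient_info` naming the field rather than guessing.

Decision logic encodes USPSTF A/B recommendations of the study era and the
bodies USPSTF defers to: JNC VII blood-pressure goals (<140/90, <130/80
with diabetes), NCEP ATP III cholesterol goals stratified by risk (LDL
< 100 mg/dL with coronary disease or an equivalent, < 130 with >= 2 risk
factors, < 160 otherwise), ADA diabetes-screening criteria (which
deliberately conflict with USPSTF's and surface as discrepancy flags), and
ACIP immunization schedules. Ten-year coronary risk is the NCEP ATP III
Framingham point score, summed from the published sex-specific tables.

## Worked example

```python
import datetime as dt
from precare import *
from precare.patient import ClinicalExtract, Observation, MedicationEntry, Event

extract = ClinicalExtract(
    patient_id="jane-0001", date_of_birth=dt.date(1955, 3, 2), sex="female",
    vitals=[Observation(code="systolic_bp", value=147, unit="mmHg", date=dt.date(2011, 4, 12)),
            Observation(code="diastolic_bp", value=92, unit="mmHg", date=dt.date(2011, 4, 12))],
    labs=[Observation(code="ldl", value=118, unit="mg/dL", date=dt.date(2011, 4, 12)),
          Observation(code="total_cholesterol", value=208, unit="mg/dL", date=dt.date(2011, 4, 12)),
          Observation(code="hdl", value=48, unit="mg/dL", date=dt.date(2011, 4, 12))],
    screening_events=[Event(code="mammogram", date=dt.date(2010, 11, 20))],
    medications=[MedicationEntry(name="lisinopril", sig="1 PO QD")],
    conditions=["hypertension"], extract_date=dt.date(2011, 5, 1))

hra = HRAResponse(answers={
    "tobacco_use": "current", "physical_activity": "insufficient",
    "diet_quality": "fair", "race_ethnicity": "white",
    "family_colorectal_cancer": True,
    "family_colorectal_cancer_age_band": "before_60",
    "family_breast_ovarian_cancer": False, "family_premature_chd": False,
    "family_other": False, "prior_abnormal_pap": False,
    "prior_abnormal_mammogram": False, "prior_abnormal_colonoscopy": False,
}, response_date=dt.date(2011, 5, 1))

profile = merge(extract, hra)
page = build_summary(profile, default_ruleset(), dt.date(2011, 6, 1))
for item in page.needs_now:
    print(item.cue, "|", item.label)
print(ten_year_chd_risk(profile, as_of=dt.date(2011, 6, 1)))
```

prints (abridged):

```
action | Due now: screening for colon cancer
action | Due now: help with quitting smoking
action | Above goal: total cholesterol (goal: total cholesterol below 200 mg/dL)
action | Above goal: systolic (top-number) blood pressure (goal: systolic pressure below 140 mmHg)
score_id='ten_year_chd' value=17.0 points=22 inputs_used=[...]
```

Jane, 56, is due for colon-cancer screening because her reported family
history moved the start age to 40 and no colonoscopy is on record; her
smoking answer gates the cessation-counseling service on; her cholesterol
and blood pressure are flagged against *her* goals (treated hypertension);
and her ATP III point total (22) maps to a 17% ten-year coronary risk.
Her mammogram from 2010-11 leaves breast-cancer screening `up_to_date`
until 2012-11. `translate_term("1 PO QD")` renders her prescription sig as
"take 1 pill once daily by mouth".

The same flow is available from the shell:

```bash
precare evaluate --extract jane.json --hra jane-hra.json \
    --as-of 2011-06-01 --out out/ --format markdown
precare simulate --n 200 --seed 7 --out panel/
precare panel --panel-dir panel/ --as-of 2011-06-01 --out report/
precare metrics --eligible 50124 --accounts 7235   # -> 14.4
```

`evaluate` logs the five pipeline components (collect, integrate,
interpret, recommend, act) and writes the summary page, the 18 detailed
messages, and the clinician summary as JSON (plus markdown renderings).

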