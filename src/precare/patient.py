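"""Patient data model: the EMR clinical extract, the health risk assessment
(HRA), and their reconciliation into a single profile.

Two information sources feed the engine.  The *clinical extract* is a snapshot
of the structured data a primary-care EMR holds about one patient:
demographics, vitals, laboratory results, immunization and screening-test
dates with structured result flags, medications, and problem-list conditions.
The *health risk assessment* is a short patient questionnaire covering the
things EMRs record poorly or not at all — health behaviors, race/ethnicity,
family history with the specificity screening rules need (e.g. a first-degree
relative with colorectal cancer diagnosed before age 60), and prior abnormal
pap smears, mammograms, or colonoscopies, whose reports typically live as
free text the engine cannot interpret.

The merge policy is asymmetric by design: for HRA-domain facts the patient is
the authority (provenance ``patient``); for labs, vitals, and service dates
the EMR is (provenance ``emr``).  A declined answer leaves the field
``absent``, which downstream drives the ``missing_info`` service status
rather than a guess.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from enum import Enum
from typing import Any, NamedTuple, Optional, Union

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from ._dates import compute_age as _compute_age
from ._dates import parse_date
from .errors import SchemaError

DECLINED = "declined"

# Canonical units per analyte/vital code. Inputs in other units are rejected,
# not converted: conversion is a reader concern and silent conversion would
# make rule evaluation depend on upstream formatting.
CANONICAL_UNITS: dict[str, str] = {
    "ldl": "mg/dL",
    "hdl": "mg/dL",
    "total_cholesterol": "mg/dL",
    "triglycerides": "mg/dL",
    "fasting_glucose": "mg/dL",
    "hba1c": "%",
    "psa": "ng/mL",
    "systolic_bp": "mmHg",
    "diastolic_bp": "mmHg",
    "height": "cm",
    "weight": "kg",
}

#: The 3 behavior items of the HRA. The deployed questionnaire's wording is
#: not public; these identifiers and answer scales are placeholders chosen to
#: cover the health-behavior services, and are configurable via HRA_CHOICES.
BEHAVIOR_ITEMS: tuple[str, ...] = ("tobacco_use", "physical_activity", "diet_quality")

#: The 9 history/demographic items (race/ethnicity, family history, prior
#: abnormal results).  The domain split into exactly nine items is a package
#: convention; the questionnaire covers these domains.
HISTORY_ITEMS: tuple[str, ...] = (
    "race_ethnicity",
    "family_colorectal_cancer",
    "family_colorectal_cancer_age_band",
    "family_breast_ovarian_cancer",
    "family_premature_chd",
    "family_other",
    "prior_abnormal_pap",
    "prior_abnormal_mammogram",
    "prior_abnormal_colonoscopy",
)

HRA_ITEMS: tuple[str, ...] = BEHAVIOR_ITEMS + HISTORY_ITEMS

#: Allowed answers for choice-typed items; items absent here are boolean.
HRA_CHOICES: dict[str, tuple[str, ...]] = {
    "tobacco_use": ("never", "former", "current"),
    "physical_activity": ("active", "insufficient", "inactive"),
    "diet_quality": ("good", "fair", "poor"),
    "race_ethnicity": (
        "white", "black", "hispanic", "asian", "native_american",
        "pacific_islander", "multiracial", "other",
    ),
    "family_colorectal_cancer_age_band": ("before_60", "60_or_later", "not_applicable"),
}

#: Elements of the minimum clinical dataset the rules need, with the check
#: used to decide presence.
MINIMUM_DATASET_ELEMENTS: tuple[str, ...] = (
    "patient_id",
    "date_of_birth",
    "sex",
    "blood_pressure",
    "height",
    "weight",
    "lipid_panel",
    "glucose_or_hba1c",
    "immunizations",
    "screening_events",
    "medications",
    "conditions",
    "extract_date",
)


class Sex(str, Enum):
    female = "female"
    male = "male"
    unknown = "unknown"


class ResultFlag(str, Enum):
    normal = "normal"
    abnormal = "abnormal"
    text_only = "text_only"
    unknown = "unknown"


class Provenance(str, Enum):
    emr = "emr"
    patient = "patient"
    absent = "absent"


class Observation(BaseModel):
    """One dated, unit-tagged numeric measurement (lab or vital)."""

    model_config = ConfigDict(extra="ignore", frozen=True)

    code: str
    value: float
    unit: str
    date: dt.date

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("value must be finite")
        return v

    @field_validator("unit")
    @classmethod
    def _unit_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("unit must be non-empty")
        return v

    @model_validator(mode="after")
    def _unit_canonical(self) -> "Observation":
        expected = CANONICAL_UNITS.get(self.code)
        if expected is not None and self.unit != expected:
            raise ValueError(
                f"unknown unit {self.unit!r} for {self.code} (expected {expected!r})"
            )
        return self


class Event(BaseModel):
    """A dated service delivery: an immunization or a screening test."""

    model_config = ConfigDict(extra="ignore", frozen=True)

    code: str
    date: dt.date
    structured_result: ResultFlag = ResultFlag.unknown


class MedicationEntry(BaseModel):
    model_config = ConfigDict(extra="ignore", frozen=True)

    name: str
    sig: str = ""


class ClinicalExtract(BaseModel):
    """EMR-sourced snapshot of one patient's prevention-relevant data."""

    model_config = ConfigDict(extra="ignore")

    patient_id: str
    date_of_birth: dt.date
    sex: Sex = Sex.unknown
    vitals: list[Observation] = []
    labs: list[Observation] = []
    screening_events: list[Event] = []
    immunizations: list[Event] = []
    medications: list[MedicationEntry] = []
    conditions: list[str] = []
    extract_date: dt.date

    @field_validator("patient_id")
    @classmethod
    def _id_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("patient_id must be non-empty")
        return v

    @model_validator(mode="after")
    def _dates_precede_extract(self) -> "ClinicalExtract":
        for group in (self.vitals, self.labs, self.screening_events, self.immunizations):
            for item in group:
                if item.date > self.extract_date:
                    raise ValueError(
                        f"{item.code} dated {item.date} after extract_date {self.extract_date}"
                    )
        return self

    def latest(self, code: str) -> Optional[Observation]:
        """Most recent observation with the given code, or None."""
        matches = [o for o in self.vitals + self.labs if o.code == code]
        return max(matches, key=lambda o: o.date) if matches else None

    def history(self, code: str) -> list[Observation]:
        """All observations with the given code, date-ascending."""
        return sorted(
            (o for o in self.vitals + self.labs if o.code == code),
            key=lambda o: o.date,
        )

    def events_for(self, codes: tuple[str, ...] | list[str]) -> list[Event]:
        wanted = set(codes)
        pool = self.screening_events + self.immunizations
        return sorted((e for e in pool if e.code in wanted), key=lambda e: e.date)


Answer = Union[bool, str]


class HRAResponse(BaseModel):
    """Answers to the 12-item questionnaire (3 behavior + 9 history items).

    Every item must appear; any item may carry the literal answer
    ``"declined"``.
    """

    model_config = ConfigDict(extra="forbid")

    answers: dict[str, Answer]
    response_date: dt.date

    @field_validator("answers")
    @classmethod
    def _validate_items(cls, answers: dict[str, Answer]) -> dict[str, Answer]:
        missing = [i for i in HRA_ITEMS if i not in answers]
        extra = [k for k in answers if k not in HRA_ITEMS]
        if missing or extra:
            raise ValueError(f"HRA item mismatch: missing={missing} unexpected={extra}")
        for item, value in answers.items():
            if value == DECLINED:
                continue
            choices = HRA_CHOICES.get(item)
            if choices is not None:
                if not isinstance(value, str) or value not in choices:
                    raise ValueError(f"{item}: expected one of {choices}, got {value!r}")
            else:
                if not isinstance(value, bool):
                    raise ValueError(f"{item}: expected a boolean, got {value!r}")
        return answers

    def behavior_items(self) -> dict[str, Answer]:
        return {k: self.answers[k] for k in BEHAVIOR_ITEMS}

    def history_items(self) -> dict[str, Answer]:
        return {k: self.answers[k] for k in HISTORY_ITEMS}


class Correction(BaseModel):
    field: str
    old_value: Any = None
    new_value: Any = None


class CompletenessReport(BaseModel):
    """Presence of each minimum-dataset element plus patient-routing flags."""

    elements: dict[str, bool]
    ask_patient: list[str] = []

    @property
    def complete(self) -> bool:
        return all(self.elements.values())

    @property
    def missing(self) -> list[str]:
        return [k for k, v in self.elements.items() if not v]


class HRAItemStatus(BaseModel):
    item_id: str
    confirm_only: bool = False
    prior_answer: Optional[Answer] = None


class FieldValue(NamedTuple):
    """A profile field's value together with where it came from."""

    value: Any
    provenance: Provenance

    def known(self) -> bool:
        return self.provenance != Provenance.absent


class PatientProfile(BaseModel):
    """Reconciled merge of the clinical extract and the HRA.

    Field access goes through :meth:`field`, which returns the value with its
    provenance tag; rule evaluation treats ``absent`` provenance as "cannot
    decide" rather than assuming a default.
    """

    extract: ClinicalExtract
    hra: HRAResponse
    provenance: dict[str, Provenance]
    corrections: list[Correction] = []

    @property
    def patient_id(self) -> str:
        return self.extract.patient_id

    @property
    def sex(self) -> Sex:
        return self.extract.sex

    def age(self, as_of: dt.date) -> int:
        return _compute_age(self.extract.date_of_birth, as_of)

    def field(self, name: str, as_of: Optional[dt.date] = None) -> FieldValue:
        """Resolve a named profile field to (value, provenance).

        Supports the raw HRA items, EMR condition predicates
        (``has_<condition>``), derived booleans used by the rules
        (``smoker``, ``ever_smoker``, ``family_colorectal_cancer_before_60``,
        ``on_bp_medication``), ``sex``, ``age``, ``bmi``, and latest-value
        lookups for any canonical analyte code.
        """
        if name == "sex":
            if self.extract.sex == Sex.unknown:
                return FieldValue(value=None, provenance=Provenance.absent)
            return FieldValue(value=self.extract.sex.value, provenance=Provenance.emr)
        if name == "age":
            as_of = as_of or self.extract.extract_date
            return FieldValue(value=self.age(as_of), provenance=Provenance.emr)
        if name == "bmi":
            h = self.extract.latest("height")
            w = self.extract.latest("weight")
            if h is None or w is None or h.value <= 0:
                return FieldValue(value=None, provenance=Provenance.absent)
            bmi = w.value / (h.value / 100.0) ** 2
            return FieldValue(value=round(bmi, 1), provenance=Provenance.emr)
        if name == "smoker":
            base = self.field("tobacco_use")
            if not base.known():
                return base
            return FieldValue(value=base.value == "current", provenance=base.provenance)
        if name == "ever_smoker":
            base = self.field("tobacco_use")
            if not base.known():
                return base
            return FieldValue(
                value=base.value in ("current", "former"), provenance=base.provenance
            )
        if name == "family_colorectal_cancer_before_60":
            fcc = self.field("family_colorectal_cancer")
            if not fcc.known():
                return fcc
            if fcc.value is False:
                return FieldValue(value=False, provenance=fcc.provenance)
            band = self.field("family_colorectal_cancer_age_band")
            if not band.known():
                return FieldValue(value=None, provenance=Provenance.absent)
            return FieldValue(value=band.value == "before_60", provenance=Provenance.patient)
        if name == "on_bp_medication":
            on_med = any(
                m.name.lower() in ANTIHYPERTENSIVES for m in self.extract.medications
            )
            return FieldValue(value=on_med, provenance=Provenance.emr)
        if name.startswith("has_"):
            condition = name[4:]
            return FieldValue(
                value=condition in self.extract.conditions, provenance=Provenance.emr
            )
        if name in HRA_ITEMS:
            value = self.hra.answers.get(name, DECLINED)
            tag = self.provenance.get(name, Provenance.absent)
            if value == DECLINED or tag == Provenance.absent:
                return FieldValue(value=None, provenance=Provenance.absent)
            return FieldValue(value=value, provenance=tag)
        if name in CANONICAL_UNITS:
            obs = self.extract.latest(name)
            if obs is None:
                return FieldValue(value=None, provenance=Provenance.absent)
            return FieldValue(value=obs.value, provenance=Provenance.emr)
        return FieldValue(value=None, provenance=Provenance.absent)

    def record_correction(self, field: str, old_value: Any, new_value: Any) -> None:
        """Append a patient edit; the list is append-only within a session."""
        self.corrections.append(
            Correction(field=field, old_value=old_value, new_value=new_value)
        )


#: Medication names counted as blood-pressure treatment for risk scoring.
ANTIHYPERTENSIVES = {
    "lisinopril", "enalapril", "losartan", "valsartan", "amlodipine",
    "hydrochlorothiazide", "chlorthalidone", "metoprolol", "atenolol",
}

#: Screening-service codes whose reports are narrative text in practice, so a
#: text_only structured result routes the "prior abnormal?" question to the
#: patient questionnaire.
TEXT_REPORT_SERVICES = {
    "pap_smear": "prior_abnormal_pap",
    "mammogram": "prior_abnormal_mammogram",
    "colonoscopy": "prior_abnormal_colonoscopy",
    "sigmoidoscopy": "prior_abnormal_colonoscopy",
}


def load_extract(document: Union[str, bytes, dict]) -> ClinicalExtract:
    """Parse and validate a clinical-extract JSON document.

    Accepts a JSON string/bytes or an already-decoded mapping.  Unknown
    vendor fields are preserved by the schema but ignored.  Raises
    :class:`SchemaError` naming the offending field on validation failure.
    """
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"extract is not valid JSON: {exc}") from exc
    if not isinstance(document, dict):
        raise SchemaError("extract document must be a JSON object")
    try:
        return ClinicalExtract.model_validate(document)
    except ValidationError as exc:
        fields = sorted({str(err["loc"][0]) if err["loc"] else "?" for err in exc.errors()})
        raise SchemaError(
            f"invalid clinical extract: {'; '.join(fields)}", fields=fields
        ) from exc


def load_hra(document: Union[str, bytes, dict]) -> HRAResponse:
    """Parse and validate an HRA response JSON document."""
    if isinstance(document, (str, bytes)):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"HRA is not valid JSON: {exc}") from exc
    if not isinstance(document, dict):
        raise SchemaError("HRA document must be a JSON object")
    try:
        return HRAResponse.model_validate(document)
    except ValidationError as exc:
        fields = sorted({str(err["loc"][-1]) if err["loc"] else "?" for err in exc.errors()})
        detail = "; ".join(
            f"{'.'.join(map(str, err['loc'])) or '?'}: {err['msg']}" for err in exc.errors()
        )
        raise SchemaError(f"invalid HRA response: {detail}", fields=fields) from exc


def validate_minimum_dataset(extract: ClinicalExtract) -> CompletenessReport:
    """Report which minimum-dataset elements are present.

    Also flags screening events whose structured result is narrative text
    only ("text_only") as not machine-interpretable, routing the
    corresponding prior-abnormal question to the patient.  Never mutates its
    input and never raises: completeness is a report, not an exception.
    """
    has_lab = lambda *codes: any(extract.latest(c) is not None for c in codes)
    elements = {
        "patient_id": bool(extract.patient_id),
        "date_of_birth": True,  # parse-time mandatory
        "sex": extract.sex != Sex.unknown,
        "blood_pressure": has_lab("systolic_bp") and has_lab("diastolic_bp"),
        "height": has_lab("height"),
        "weight": has_lab("weight"),
        "lipid_panel": has_lab("total_cholesterol") and has_lab("hdl"),
        "glucose_or_hba1c": has_lab("fasting_glucose", "hba1c"),
        "immunizations": len(extract.immunizations) > 0,
        "screening_events": len(extract.screening_events) > 0,
        "medications": len(extract.medications) > 0,
        "conditions": len(extract.conditions) > 0,
        "extract_date": True,
    }
    ask_patient = sorted(
        {
            TEXT_REPORT_SERVICES[e.code]
            for e in extract.screening_events
            if e.structured_result == ResultFlag.text_only and e.code in TEXT_REPORT_SERVICES
        }
    )
    return CompletenessReport(elements=elements, ask_patient=ask_patient)


def pending_hra_items(
    extract: ClinicalExtract,
    prior_hra: Optional[HRAResponse] = None,
    as_of: Optional[dt.date] = None,
    staleness_months: int = 12,
) -> list[HRAItemStatus]:
    """The 12 HRA items to administer.

    The questionnaire is always given in full (the engine asks patients about
    everything EMRs record poorly); items answered in a prior HRA are marked
    confirm-only with the prior answer attached.  Answers older than the
    staleness window are still only confirm-only, never silently reused as
    authoritative.
    """
    del staleness_months  # staleness affects merge authority, not the item list
    del as_of
    prior = prior_hra.answers if prior_hra is not None else {}
    items = []
    for item in HRA_ITEMS:
        answered = item in prior and prior[item] != DECLINED
        items.append(
            HRAItemStatus(
                item_id=item,
                confirm_only=answered,
                prior_answer=prior.get(item) if answered else None,
            )
        )
    return items


def merge(extract: ClinicalExtract, hra: HRAResponse) -> PatientProfile:
    """Reconcile extract and HRA into a profile with per-field provenance.

    HRA-domain fields take the patient's answer (provenance ``patient``);
    labs, vitals, and event dates keep the EMR value (``emr``); a declined
    answer leaves the field ``absent``.  The function is pure and idempotent:
    the same inputs always produce an identical profile.
    """
    provenance: dict[str, Provenance] = {}
    for item in HRA_ITEMS:
        answer = hra.answers[item]
        provenance[item] = (
            Provenance.absent if answer == DECLINED else Provenance.patient
        )
    for code in CANONICAL_UNITS:
        if extract.latest(code) is not None:
            provenance[code] = Provenance.emr
    return PatientProfile(extract=extract, hra=hra, provenance=provenance)


compute_age = _compute_age
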