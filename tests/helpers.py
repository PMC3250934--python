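"""Builders for compact test patients."""

from __future__ import annotations

import datetime as dt
from typing import Optional

from precare.patient import (
    HRA_ITEMS,
    ClinicalExtract,
    Event,
    HRAResponse,
    MedicationEntry,
    Observation,
    PatientProfile,
    merge,
)

AS_OF = dt.date(2011, 6, 1)
EXTRACT_DATE = dt.date(2011, 5, 1)

BENIGN_ANSWERS = {
    "tobacco_use": "never",
    "physical_activity": "active",
    "diet_quality": "good",
    "race_ethnicity": "white",
    "family_colorectal_cancer": False,
    "family_colorectal_cancer_age_band": "not_applicable",
    "family_breast_ovarian_cancer": False,
    "family_premature_chd": False,
    "family_other": False,
    "prior_abnormal_pap": False,
    "prior_abnormal_mammogram": False,
    "prior_abnormal_colonoscopy": False,
}
assert set(BENIGN_ANSWERS) == set(HRA_ITEMS)


def dob_for_age(age: int, as_of: dt.date = AS_OF) -> dt.date:
    """A birth date giving exactly `age` completed years at `as_of`."""
    return dt.date(as_of.year - age, as_of.month, as_of.day) - dt.timedelta(days=100)


def make_extract(
    sex: str = "female",
    age: int = 55,
    conditions: Optional[list[str]] = None,
    labs: Optional[list[Observation]] = None,
    vitals: Optional[list[Observation]] = None,
    screening_events: Optional[list[Event]] = None,
    immunizations: Optional[list[Event]] = None,
    medications: Optional[list[MedicationEntry]] = None,
    patient_id: str = "T-0001",
    extract_date: dt.date = EXTRACT_DATE,
) -> ClinicalExtract:
    return ClinicalExtract(
        patient_id=patient_id,
        date_of_birth=dob_for_age(age),
        sex=sex,
        conditions=conditions or [],
        labs=labs or [],
        vitals=vitals or [],
        screening_events=screening_events or [],
        immunizations=immunizations or [],
        medications=medications or [],
        extract_date=extract_date,
    )


def make_hra(response_date: dt.date = EXTRACT_DATE, **overrides) -> HRAResponse:
    answers = {**BENIGN_ANSWERS, **overrides}
    return HRAResponse(answers=answers, response_date=response_date)


def make_profile(
    sex: str = "female", age: int = 55, hra_overrides: Optional[dict] = None, **extract_kwargs
) -> PatientProfile:
    extract = make_extract(sex=sex, age=age, **extract_kwargs)
    hra = make_hra(**(hra_overrides or {}))
    return merge(extract, hra)


def obs(code: str, value: float, date: dt.date = dt.date(2011, 4, 1)) -> Observation:
    from precare.patient import CANONICAL_UNITS

    return Observation(code=code, value=value, unit=CANONICAL_UNITS[code], date=date)
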