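"""Brute-force re-implementation of the shipped rule table.

Written independently of the engine as straight-line per-service logic over
plain facts, so the two can disagree.  Facts use None for "patient declined /
unknown"; a None that decides the verdict yields "insufficient_info".
"""

from __future__ import annotations

from typing import Optional


def oracle_verdict(
    service_id: str,
    sex: str,
    age: int,
    fam_crc_before_60: Optional[bool],
    tobacco: Optional[str],  # never | former | current | None
    diet: Optional[str],  # good | fair | poor | None
    activity: Optional[str],  # active | insufficient | inactive | None
    has_hypertension: bool,
    has_diabetes: bool,
    has_hyperlipidemia: bool,
    sbp: float,
) -> str:
    if service_id == "breast_cancer_screening":
        if sex != "female" or age < 40 or age > 74:
            return "not_indicated"
        return "uncertain" if age <= 49 else "indicated"

    if service_id == "cervical_cancer_screening":
        return "indicated" if sex == "female" and 21 <= age <= 65 else "not_indicated"

    if service_id == "colorectal_cancer_screening":
        if age > 75:
            return "not_indicated"
        if age >= 50:
            return "indicated"
        if age >= 40:
            if fam_crc_before_60 is None:
                return "insufficient_info"
            return "indicated" if fam_crc_before_60 else "not_indicated"
        return "not_indicated"

    if service_id == "prostate_cancer_screening":
        return "uncertain" if sex == "male" and 50 <= age <= 75 else "not_indicated"

    if service_id == "blood_pressure_screening":
        return "indicated" if age >= 18 else "not_indicated"

    if service_id == "cholesterol_screening":
        start = 45 if sex == "female" else 35
        if has_diabetes:
            start = 20
        return "indicated" if age >= start else "not_indicated"

    if service_id == "diabetes_screening":
        if age < 18:
            return "not_indicated"
        return "indicated" if has_hypertension or sbp >= 135 else "not_indicated"

    if service_id == "aspirin_chemoprevention":
        start = 55 if sex == "female" else 45
        return "indicated" if start <= age <= 79 else "not_indicated"

    if service_id == "aaa_screening":
        if sex != "male" or not 65 <= age <= 75:
            return "not_indicated"
        if tobacco is None:
            return "insufficient_info"
        return "indicated" if tobacco in ("current", "former") else "not_indicated"

    if service_id == "tobacco_cessation":
        if age < 18:
            return "not_indicated"
        if tobacco is None:
            return "insufficient_info"
        return "indicated" if tobacco == "current" else "not_indicated"

    if service_id == "diet_counseling":
        if age < 18:
            return "not_indicated"
        if has_hyperlipidemia:
            return "indicated"
        if diet is None:
            return "insufficient_info"
        return "indicated" if diet == "poor" else "not_indicated"

    if service_id == "physical_activity_counseling":
        if age < 18:
            return "not_indicated"
        if activity is None:
            return "insufficient_info"
        return "indicated" if activity in ("insufficient", "inactive") else "not_indicated"

    if service_id == "obesity_screening":
        return "indicated" if age >= 18 else "not_indicated"

    if service_id == "alcohol_misuse_screening":
        return "indicated" if age >= 18 else "not_indicated"

    if service_id == "influenza_vaccine":
        return "indicated" if age >= 18 else "not_indicated"

    if service_id == "pneumococcal_vaccine":
        return "indicated" if age >= 65 else "not_indicated"

    if service_id == "td_booster":
        return "indicated" if age >= 18 else "not_indicated"

    if service_id == "osteoporosis_screening":
        return "indicated" if sex == "female" and age >= 65 else "not_indicated"

    raise KeyError(service_id)
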