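"""Contextual interpretation of lab values and vitals.

A raw value with a generic reference range can mislead: an LDL of 110 mg/dL
is above goal for a patient with coronary artery disease or a risk
equivalent (NCEP ATP III goal < 100 mg/dL) but within goal for a low-risk
patient (goal < 160 mg/dL).  ``interpret_value`` therefore selects the goal
from the patient's conditions and risk-factor context and reports the goal
it actually applied, so downstream messages can explain the classification.

Thresholds: LDL goals stratified per NCEP ATP III (CHD or risk equivalent
< 100; >= 2 major risk factors < 130; otherwise < 160); blood pressure per
JNC VII (< 140/90, or < 130/80 with diabetes or chronic kidney disease);
HDL is protective, flagged low below 40 mg/dL.
"""

from __future__ import annotations

import datetime as dt
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .patient import Observation, PatientProfile, Sex


class InterpretationResult(str, Enum):
    within_goal = "within_goal"
    above_goal = "above_goal"
    below_goal = "below_goal"
    not_interpretable = "not_interpretable"


class Interpretation(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: str
    result: InterpretationResult
    goal: Optional[str] = None
    threshold: Optional[float] = None


def _risk_factor_count(profile: PatientProfile, as_of: dt.date) -> int:
    """Major CHD risk factors per ATP III (excluding LDL itself).

    Smoking, hypertension, low HDL (< 40), age (men >= 45, women >= 55),
    and family history of premature coronary disease.  Unknown factors
    count as absent — the conservative reading for goal selection.
    """
    count = 0
    smoker = profile.field("smoker")
    if smoker.known() and smoker.value:
        count += 1
    sbp = profile.extract.latest("systolic_bp")
    if "hypertension" in profile.extract.conditions or (
        sbp is not None and sbp.value >= 140
    ):
        count += 1
    hdl = profile.extract.latest("hdl")
    if hdl is not None and hdl.value < 40:
        count += 1
    age = profile.age(as_of)
    if (profile.sex == Sex.male and age >= 45) or (
        profile.sex == Sex.female and age >= 55
    ):
        count += 1
    fam = profile.field("family_premature_chd")
    if fam.known() and fam.value:
        count += 1
    return count


def _has_chd_or_equivalent(profile: PatientProfile) -> bool:
    conditions = set(profile.extract.conditions)
    return bool(
        conditions & {"coronary_artery_disease", "diabetes", "peripheral_artery_disease", "stroke"}
    )


def ldl_goal(profile: PatientProfile, as_of: dt.date) -> float:
    """ATP III LDL goal for this patient's risk stratum, in mg/dL."""
    if _has_chd_or_equivalent(profile):
        return 100.0
    if _risk_factor_count(profile, as_of) >= 2:
        return 130.0
    return 160.0


def interpret_value(
    observation: Observation,
    profile: PatientProfile,
    as_of: Optional[dt.date] = None,
) -> Interpretation:
    """Classify an observation against the patient-specific goal.

    Returns within/above/below goal plus the goal actually used; analytes
    the engine has no rule for come back ``not_interpretable``.
    """
    as_of = as_of or profile.extract.extract_date
    code, value = observation.code, observation.value
    diabetic = "diabetes" in profile.extract.conditions

    if code == "ldl":
        goal = ldl_goal(profile, as_of)
        result = (
            InterpretationResult.above_goal if value > goal else InterpretationResult.within_goal
        )
        return Interpretation(
            code=code, result=result, goal=f"LDL below {goal:.0f} mg/dL", threshold=goal
        )
    if code == "hdl":
        if value < 40:
            return Interpretation(
                code=code,
                result=InterpretationResult.below_goal,
                goal="HDL 40 mg/dL or higher",
                threshold=40.0,
            )
        return Interpretation(
            code=code,
            result=InterpretationResult.within_goal,
            goal="HDL 40 mg/dL or higher",
            threshold=40.0,
        )
    if code == "total_cholesterol":
        threshold = 200.0
        result = (
            InterpretationResult.above_goal
            if value >= threshold
            else InterpretationResult.within_goal
        )
        return Interpretation(
            code=code,
            result=result,
            goal="total cholesterol below 200 mg/dL",
            threshold=threshold,
        )
    if code == "systolic_bp":
        threshold = 130.0 if diabetic else 140.0
        result = (
            InterpretationResult.above_goal
            if value >= threshold
            else InterpretationResult.within_goal
        )
        return Interpretation(
            code=code,
            result=result,
            goal=f"systolic pressure below {threshold:.0f} mmHg",
            threshold=threshold,
        )
    if code == "diastolic_bp":
        threshold = 80.0 if diabetic else 90.0
        result = (
            InterpretationResult.above_goal
            if value >= threshold
            else InterpretationResult.within_goal
        )
        return Interpretation(
            code=code,
            result=result,
            goal=f"diastolic pressure below {threshold:.0f} mmHg",
            threshold=threshold,
        )
    if code == "fasting_glucose":
        threshold = 130.0 if diabetic else 126.0
        label = (
            "fasting glucose below 130 mg/dL (diabetes goal)"
            if diabetic
            else "fasting glucose below 126 mg/dL"
        )
        result = (
            InterpretationResult.above_goal
            if value >= threshold
            else InterpretationResult.within_goal
        )
        return Interpretation(code=code, result=result, goal=label, threshold=threshold)
    if code == "hba1c":
        threshold = 7.0 if diabetic else 6.5
        result = (
            InterpretationResult.above_goal
            if value >= threshold
            else InterpretationResult.within_goal
        )
        return Interpretation(
            code=code, result=result, goal=f"A1c below {threshold}%", threshold=threshold
        )
    if code == "psa":
        threshold = 4.0
        result = (
            InterpretationResult.above_goal
            if value > threshold
            else InterpretationResult.within_goal
        )
        return Interpretation(
            code=code, result=result, goal="PSA 4.0 ng/mL or lower", threshold=threshold
        )
    return Interpretation(code=code, result=InterpretationResult.not_interpretable)
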