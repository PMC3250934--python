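"""Ten-year coronary heart disease risk, NCEP ATP III point-score version.

This is the sex-specific Framingham point system printed in the ATP III
guideline: points for age band, total cholesterol by age band, smoking by
age band, HDL, and systolic blood pressure (treated vs untreated), summed
and mapped to a 10-year hard-CHD risk percentage.  The published table's
open-ended bins ("<1%" and ">=30%") are represented numerically as 0.5 and
30.0 so the score stays a percentage in [0, 100].

Inputs come from the merged patient profile: age and sex from demographics,
the latest total cholesterol / HDL / systolic pressure from the EMR labs and
vitals, current smoking from the patient's own behavior answer, and treated
blood pressure from the medication list.
"""

from __future__ import annotations

import bisect
import datetime as dt
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .errors import InsufficientInputsError
from .patient import PatientProfile, Sex

# Age bands shared by all age-dependent tables (lower bounds).
_AGE_BANDS = [20, 35, 40, 45, 50, 55, 60, 65, 70, 75]
# Broader bands used by the cholesterol and smoking tables.
_DECADE_BANDS = [20, 40, 50, 60, 70]

_AGE_POINTS = {
    Sex.male: [-9, -4, 0, 3, 6, 8, 10, 11, 12, 13],
    Sex.female: [-7, -3, 0, 3, 6, 8, 10, 12, 14, 16],
}

# Total cholesterol points, rows = TC bin lower bound, cols = decade band.
_TC_BINS = [160, 200, 240, 280]  # below 160 scores 0
_TC_POINTS = {
    Sex.male: [
        [4, 3, 2, 1, 0],
        [7, 5, 3, 1, 0],
        [9, 6, 4, 2, 1],
        [11, 8, 5, 3, 1],
    ],
    Sex.female: [
        [4, 3, 2, 1, 1],
        [8, 6, 4, 2, 1],
        [11, 8, 5, 3, 2],
        [13, 10, 7, 4, 2],
    ],
}

_SMOKER_POINTS = {
    Sex.male: [8, 5, 3, 1, 1],
    Sex.female: [9, 7, 4, 2, 1],
}

_SBP_BINS = [120, 130, 140, 160]  # below 120 is the reference row
_SBP_POINTS = {
    Sex.male: {"untreated": [0, 0, 1, 1, 2], "treated": [0, 1, 2, 2, 3]},
    Sex.female: {"untreated": [0, 1, 2, 3, 4], "treated": [0, 3, 4, 5, 6]},
}

# Total points -> 10-year risk percent.  Keys below/above table range clamp.
_RISK_TABLE = {
    Sex.male: {
        0: 1, 1: 1, 2: 1, 3: 1, 4: 1, 5: 2, 6: 2, 7: 3, 8: 4, 9: 5,
        10: 6, 11: 8, 12: 10, 13: 12, 14: 16, 15: 20, 16: 25,
    },
    Sex.female: {
        9: 1, 10: 1, 11: 1, 12: 1, 13: 2, 14: 2, 15: 3, 16: 4, 17: 5,
        18: 6, 19: 8, 20: 11, 21: 14, 22: 17, 23: 22, 24: 27,
    },
}
_FLOOR_RISK = 0.5  # the table's "<1%" category
_CEILING_RISK = 30.0  # the table's ">=30%" category
_CEILING_POINTS = {Sex.male: 17, Sex.female: 25}


class RiskScore(BaseModel):
    model_config = ConfigDict(frozen=True)

    score_id: str
    value: float
    points: int
    inputs_used: list[str]


def _band(bands: list[int], x: float) -> int:
    return max(0, bisect.bisect_right(bands, x) - 1)


def _hdl_points(hdl: float) -> int:
    if hdl >= 60:
        return -1
    if hdl >= 50:
        return 0
    if hdl >= 40:
        return 1
    return 2


def _points_to_risk(sex: Sex, points: int) -> float:
    table = _RISK_TABLE[sex]
    if points >= _CEILING_POINTS[sex]:
        return _CEILING_RISK
    if points < min(table):
        return _FLOOR_RISK
    return float(table[points])


def score_points(
    sex: Sex,
    age: int,
    total_cholesterol: float,
    hdl: float,
    systolic_bp: float,
    smoker: bool,
    treated_bp: bool,
) -> int:
    """Sum the ATP III point tables for explicit risk-factor values."""
    if sex not in (Sex.female, Sex.male):
        raise InsufficientInputsError(["sex"])
    age_band = _band(_AGE_BANDS, age)
    decade = _band(_DECADE_BANDS, age)
    points = _AGE_POINTS[sex][age_band]
    tc_bin = bisect.bisect_right(_TC_BINS, total_cholesterol) - 1
    if tc_bin >= 0:
        points += _TC_POINTS[sex][tc_bin][decade]
    if smoker:
        points += _SMOKER_POINTS[sex][decade]
    points += _hdl_points(hdl)
    row = "treated" if treated_bp else "untreated"
    sbp_bin = bisect.bisect_right(_SBP_BINS, systolic_bp)
    points += _SBP_POINTS[sex][row][sbp_bin]
    return points


def ten_year_chd_risk(
    profile: PatientProfile, as_of: Optional[dt.date] = None
) -> RiskScore:
    """Deterministic 10-year CHD risk percent for a merged profile.

    Raises :class:`InsufficientInputsError` naming every missing field when
    sex, total cholesterol, HDL, systolic pressure, or smoking status is
    unavailable.
    """
    as_of = as_of or profile.extract.extract_date
    missing: list[str] = []
    sex = profile.sex
    if sex == Sex.unknown:
        missing.append("sex")
    tc = profile.extract.latest("total_cholesterol")
    if tc is None:
        missing.append("total_cholesterol")
    hdl = profile.extract.latest("hdl")
    if hdl is None:
        missing.append("hdl")
    sbp = profile.extract.latest("systolic_bp")
    if sbp is None:
        missing.append("systolic_bp")
    smoker = profile.field("smoker")
    if not smoker.known():
        missing.append("smoking_status")
    if missing:
        raise InsufficientInputsError(missing)

    treated = profile.field("on_bp_medication").value is True
    age = profile.age(as_of)
    points = score_points(
        sex=sex,
        age=age,
        total_cholesterol=tc.value,  # type: ignore[union-attr]
        hdl=hdl.value,  # type: ignore[union-attr]
        systolic_bp=sbp.value,  # type: ignore[union-attr]
        smoker=bool(smoker.value),
        treated_bp=treated,
    )
    inputs = [
        "sex",
        "age",
        "total_cholesterol",
        "hdl",
        "systolic_bp",
        "smoking_status",
        "bp_treatment",
    ]
    return RiskScore(
        score_id="ten_year_chd",
        value=_points_to_risk(sex, points),
        points=points,
        inputs_used=inputs,
    )
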