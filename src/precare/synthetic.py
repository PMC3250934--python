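"""Synthetic primary-care population generator.

Everything the engine consumes can be generated here: clinical extracts,
HRA answers, practice panels with visit streams, and account-creation
behavior, so the whole pipeline is testable without any external data.  The
frame emulated is a primary-care population aged 18-75 with an office visit
during an observation window; account creation ("uptake") is Bernoulli per
visiting patient and return visits are drawn per 0-3 and 3-6 month windows.

Determinism: every patient gets their own pseudo-random stream derived from
``(seed, index)``, so panels are reproducible record-by-record regardless of
generation order, and practice-level draws use a separate stream.

Default parameters are round numbers chosen to resemble a generic adult
primary-care panel (condition prevalences, behavior mixes, screening
recency); they are deliberately not fitted to any particular practice.
"""

from __future__ import annotations

import datetime as dt
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from ._dates import add_months
from .errors import DomainError
from .patient import (
    BEHAVIOR_ITEMS,
    DECLINED,
    HRA_CHOICES,
    HRA_ITEMS,
    ClinicalExtract,
    Event,
    HRAResponse,
    MedicationEntry,
    Observation,
    Sex,
)
from .rules import Category, RuleSet, default_ruleset

_PRACTICE_STREAM_OFFSET = 1_000_000_007  # keeps practice draws off patient streams


class PopulationSpec(BaseModel):
    """Knobs for the synthetic population; deterministic given ``seed``."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(ge=1, default=100)
    seed: int = 0
    reference_date: dt.date = dt.date(2011, 5, 1)
    age_min: int = 18
    age_max: int = 75
    female_fraction: float = Field(ge=0, le=1, default=0.55)

    condition_prevalence: dict[str, float] = {
        "hypertension": 0.30,
        "hyperlipidemia": 0.25,
        "diabetes": 0.10,
        "coronary_artery_disease": 0.07,
    }
    #: probability a due-eligible patient has a prior event for a service
    prior_screening_probability: float = Field(ge=0, le=1, default=0.6)
    #: services whose reports are narrative text: probability the structured
    #: result flag is text_only rather than normal/abnormal
    text_result_probability: float = Field(ge=0, le=1, default=1.0)
    lab_panel_probability: float = Field(ge=0, le=1, default=0.85)
    declined_probability: float = Field(ge=0, le=1, default=0.03)

    tobacco_mix: dict[str, float] = {"never": 0.55, "former": 0.25, "current": 0.20}
    activity_mix: dict[str, float] = {"active": 0.40, "insufficient": 0.35, "inactive": 0.25}
    diet_mix: dict[str, float] = {"good": 0.30, "fair": 0.45, "poor": 0.25}

    family_history_probability: dict[str, float] = {
        "family_colorectal_cancer": 0.06,
        "family_breast_ovarian_cancer": 0.08,
        "family_premature_chd": 0.10,
        "family_other": 0.15,
    }
    crc_before_60_fraction: float = Field(ge=0, le=1, default=0.4)
    prior_abnormal_probability: dict[str, float] = {
        "prior_abnormal_pap": 0.05,
        "prior_abnormal_mammogram": 0.08,
        "prior_abnormal_colonoscopy": 0.07,
    }

    @field_validator("condition_prevalence", "family_history_probability",
                     "prior_abnormal_probability", "tobacco_mix", "activity_mix",
                     "diet_mix")
    @classmethod
    def _probs_in_range(cls, v: dict[str, float]) -> dict[str, float]:
        for key, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {key} must be in [0, 1]")
        return v


class AdoptionModel(BaseModel):
    """Account creation and return-visit behavior during the window."""

    model_config = ConfigDict(extra="forbid")

    uptake_probability: float = Field(ge=0, le=1, default=0.144)
    return_0_3_probability: float = Field(ge=0, le=1, default=0.49)
    return_3_6_probability: float = Field(ge=0, le=1, default=0.10)
    observation_months: int = Field(ge=1, default=6)
    #: the spread of per-practice uptake used by multi-practice simulation
    practice_uptake_range: tuple[float, float] = (0.015, 0.283)


class PracticePanel(BaseModel):
    """One simulated practice: who visited, who enrolled, who returned."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    practice_id: int
    spec: PopulationSpec
    patients: pd.DataFrame  # patient_id, index, visit_date, account, return_0_3, return_3_6

    @property
    def n_visitors(self) -> int:
        return len(self.patients)

    @property
    def n_accounts(self) -> int:
        return int(self.patients["account"].sum())


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    labels = list(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    return str(rng.choice(labels, p=probs))


def _days_back(rng: np.random.Generator, reference: dt.date, max_days: int) -> dt.date:
    return reference - dt.timedelta(days=int(rng.integers(1, max(2, max_days))))


def generate_patient(
    spec: PopulationSpec, index: int, ruleset: Optional[RuleSet] = None
) -> tuple[ClinicalExtract, HRAResponse]:
    """Draw one patient's clinical extract and HRA answers.

    Deterministic in ``(spec.seed, index)``.  Emitted records always satisfy
    the extract and HRA schemas; screening events for narrative-report
    services carry a text_only flag with the configured probability, which
    routes the corresponding prior-abnormal question to the patient.
    """
    rng = np.random.default_rng([spec.seed, index])
    ruleset = ruleset or default_ruleset()
    ref = spec.reference_date

    age = int(rng.integers(spec.age_min, spec.age_max + 1))
    dob = ref - dt.timedelta(days=int(age * 365.2425 + rng.integers(0, 360)))
    sex = Sex.female if rng.random() < spec.female_fraction else Sex.male

    conditions = [
        c for c, p in spec.condition_prevalence.items() if rng.random() < p
    ]

    vitals: list[Observation] = []
    labs: list[Observation] = []
    vital_date = _days_back(rng, ref, 365)
    height = float(rng.normal(162 if sex == Sex.female else 176, 7))
    bmi = float(np.clip(rng.normal(27.5, 5.0), 17, 55))
    weight = round(bmi * (height / 100) ** 2, 1)
    sbp = float(np.clip(rng.normal(126, 16) + (14 if "hypertension" in conditions else 0), 90, 210))
    dbp = float(np.clip(rng.normal(79, 10) + (6 if "hypertension" in conditions else 0), 50, 130))
    vitals += [
        Observation(code="height", value=round(height, 1), unit="cm", date=vital_date),
        Observation(code="weight", value=weight, unit="kg", date=vital_date),
        Observation(code="systolic_bp", value=round(sbp), unit="mmHg", date=vital_date),
        Observation(code="diastolic_bp", value=round(dbp), unit="mmHg", date=vital_date),
    ]

    if rng.random() < spec.lab_panel_probability:
        n_panels = int(rng.integers(1, 4))
        for k in range(n_panels):
            lab_date = _days_back(rng, ref, 365 * (k + 1))
            bump = 25 if "hyperlipidemia" in conditions else 0
            tc = float(np.clip(rng.normal(205 + bump, 30), 120, 380))
            hdl = float(np.clip(rng.normal(52, 13), 22, 100))
            ldl = float(np.clip(tc - hdl - rng.normal(30, 10), 40, 280))
            labs += [
                Observation(code="total_cholesterol", value=round(tc), unit="mg/dL", date=lab_date),
                Observation(code="hdl", value=round(hdl), unit="mg/dL", date=lab_date),
                Observation(code="ldl", value=round(ldl), unit="mg/dL", date=lab_date),
            ]
    if rng.random() < spec.lab_panel_probability:
        glu_date = _days_back(rng, ref, 540)
        glu = float(np.clip(rng.normal(128 if "diabetes" in conditions else 96, 16), 60, 350))
        labs.append(
            Observation(code="fasting_glucose", value=round(glu), unit="mg/dL", date=glu_date)
        )

    screening_events: list[Event] = []
    immunizations: list[Event] = []
    text_services = {"pap_smear", "mammogram", "colonoscopy", "sigmoidoscopy"}
    for rule in ruleset.services:
        if not rule.event_codes:
            continue
        if sex not in rule.applicable_sex:
            continue
        start = rule.age_min if rule.age_min is not None else spec.age_min
        if age < start:
            continue
        if rng.random() >= spec.prior_screening_probability:
            continue
        code = rule.event_codes[0]
        interval = rule.interval_months or 120
        when = _days_back(rng, ref, int(interval * 30.44 * 1.5))
        if code in text_services and rng.random() < spec.text_result_probability:
            flag = "text_only"
        else:
            flag = "normal" if rng.random() < 0.9 else "abnormal"
        event = Event(code=code, date=when, structured_result=flag)
        if rule.category == Category.vaccines:
            immunizations.append(event)
        else:
            screening_events.append(event)

    medications: list[MedicationEntry] = []
    if "hypertension" in conditions:
        medications.append(MedicationEntry(name="lisinopril", sig="1 PO QD"))
    if "hyperlipidemia" in conditions:
        medications.append(MedicationEntry(name="simvastatin", sig="1 PO QD"))
    if "diabetes" in conditions:
        medications.append(MedicationEntry(name="metformin", sig="2 PO BID"))

    extract = ClinicalExtract(
        patient_id=f"P{spec.seed}-{index:06d}",
        date_of_birth=dob,
        sex=sex,
        vitals=vitals,
        labs=labs,
        screening_events=screening_events,
        immunizations=immunizations,
        medications=medications,
        conditions=conditions,
        extract_date=ref,
    )

    answers: dict[str, object] = {}
    answers["tobacco_use"] = _choice(rng, spec.tobacco_mix)
    answers["physical_activity"] = _choice(rng, spec.activity_mix)
    answers["diet_quality"] = _choice(rng, spec.diet_mix)
    answers["race_ethnicity"] = _choice(
        rng,
        {"white": 0.62, "black": 0.18, "hispanic": 0.12, "asian": 0.05, "other": 0.03},
    )
    for item, p in spec.family_history_probability.items():
        answers[item] = bool(rng.random() < p)
    if answers["family_colorectal_cancer"]:
        answers["family_colorectal_cancer_age_band"] = (
            "before_60" if rng.random() < spec.crc_before_60_fraction else "60_or_later"
        )
    else:
        answers["family_colorectal_cancer_age_band"] = "not_applicable"
    for item, p in spec.prior_abnormal_probability.items():
        answers[item] = bool(rng.random() < p)
    for item in HRA_ITEMS:
        if rng.random() < spec.declined_probability:
            answers[item] = DECLINED
    hra = HRAResponse(answers=answers, response_date=ref)
    return extract, hra


def generate_practice(
    spec: PopulationSpec,
    adoption: AdoptionModel,
    practice_id: int = 0,
    uptake_probability: Optional[float] = None,
) -> PracticePanel:
    """Simulate one practice's visit stream and account creation.

    Every patient in the spec visits once during the observation window;
    account creation is Bernoulli at the practice uptake probability, and
    return visits are drawn for account holders per window probabilities.
    Draws are vectorized from a dedicated practice-level stream.
    """
    p = adoption.uptake_probability if uptake_probability is None else uptake_probability
    rng = np.random.default_rng([spec.seed, _PRACTICE_STREAM_OFFSET + practice_id])
    n = spec.n_patients
    window_days = int(adoption.observation_months * 30.44)
    visit_offsets = rng.integers(0, window_days, size=n)
    accounts = rng.random(n) < p
    r03 = (rng.random(n) < adoption.return_0_3_probability) & accounts
    r36 = (rng.random(n) < adoption.return_3_6_probability) & accounts
    start = spec.reference_date
    patients = pd.DataFrame(
        {
            "index": np.arange(n),
            "patient_id": [f"PR{practice_id}-{spec.seed}-{i:06d}" for i in range(n)],
            "visit_date": [start + dt.timedelta(days=int(d)) for d in visit_offsets],
            "account": accounts,
            "return_0_3": r03,
            "return_3_6": r36,
        }
    )
    return PracticePanel(practice_id=practice_id, spec=spec, patients=patients)


def uptake_metrics(eligible_count: int, account_count: int) -> float:
    """Percent of eligible visiting patients who created an account.

    Half-up rounded to one decimal; e.g. 7,235 of 50,124 -> 14.4.
    """
    if eligible_count <= 0:
        raise DomainError("eligible_count must be positive")
    if not 0 <= account_count <= eligible_count:
        raise DomainError("account_count must be between 0 and eligible_count")
    pct = Decimal(100 * account_count) / Decimal(eligible_count)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def practice_range(uptakes: list[float]) -> tuple[float, float]:
    """Min and max per-practice uptake percent across a set of practices."""
    if not uptakes:
        raise DomainError("need at least one practice uptake value")
    return (min(uptakes), max(uptakes))


def simulate_practices(
    spec: PopulationSpec,
    adoption: AdoptionModel,
    n_practices: int = 14,
) -> pd.DataFrame:
    """Simulate a network of practices with heterogeneous uptake.

    Per-practice uptake probabilities are spaced evenly across
    ``adoption.practice_uptake_range`` so the simulated spread brackets the
    configured heterogeneity; each practice gets its own visit panel.
    Returns one row per practice with eligible, account, and uptake columns.
    """
    lo, hi = adoption.practice_uptake_range
    probs = np.linspace(lo, hi, n_practices)
    rows = []
    for pid, p in enumerate(probs):
        panel = generate_practice(spec, adoption, practice_id=pid, uptake_probability=float(p))
        rows.append(
            {
                "practice_id": pid,
                "uptake_probability": float(p),
                "eligible": panel.n_visitors,
                "accounts": panel.n_accounts,
                "uptake_percent": uptake_metrics(panel.n_visitors, panel.n_accounts),
                "return_0_3": int(panel.patients["return_0_3"].sum()),
                "return_3_6": int(panel.patients["return_3_6"].sum()),
            }
        )
    return pd.DataFrame(rows)
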