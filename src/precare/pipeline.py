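"""The five-component pipeline tying the modules together.

One evaluation run moves through five named stages, in order: *collect*
patient information (parse and validate the inputs, administer the HRA),
*integrate* existing clinical data (reconcile extract and HRA into a
profile), *interpret* the information in clinical context (value
interpretation and risk scoring), *recommend* (eligibility, statuses, the
summary page), and *act* (detailed messages, the clinician summary, and
discrepancy flags for shared decisions).
"""

from __future__ import annotations

import datetime as dt
from typing import Callable, Optional, Union

from pydantic import BaseModel, ConfigDict

from .errors import InsufficientInputsError, OrderingError
from .framingham import RiskScore, ten_year_chd_risk
from .interpret import Interpretation, interpret_value
from .longitudinal import ClinicianSummary, make_clinician_summary
from .patient import (
    CANONICAL_UNITS,
    CompletenessReport,
    PatientProfile,
    load_extract,
    load_hra,
    merge,
    pending_hra_items,
    validate_minimum_dataset,
)
from .recommend import DetailedMessage, SummaryPage, build_message, build_summary
from .rules import RuleSet, default_ruleset

#: The five pipeline components, in execution order.
PIPELINE_STAGES: tuple[str, ...] = (
    "collect",
    "integrate",
    "interpret",
    "recommend",
    "act",
)


class PipelineResult(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    stages: list[str]
    completeness: CompletenessReport
    profile: PatientProfile
    interpretations: dict[str, Interpretation]
    risk_score: Optional[RiskScore] = None
    summary: SummaryPage
    messages: dict[str, DetailedMessage]
    clinician_summary: ClinicianSummary


def run_pipeline(
    extract_doc: Union[str, bytes, dict],
    hra_doc: Union[str, bytes, dict],
    as_of: dt.date,
    ruleset: Optional[RuleSet] = None,
    log: Optional[Callable[[str], None]] = None,
) -> PipelineResult:
    """Run collect -> integrate -> interpret -> recommend -> act for one patient.

    ``log`` receives each stage name as it starts.  Raises
    :class:`OrderingError` when ``as_of`` precedes the extract date, and the
    input loaders' schema errors propagate with field names attached.
    """
    ruleset = ruleset or default_ruleset()
    stages: list[str] = []

    def stage(name: str) -> None:
        stages.append(name)
        if log is not None:
            log(name)

    stage("collect")
    extract = load_extract(extract_doc)
    hra = load_hra(hra_doc)
    if as_of < extract.extract_date:
        raise OrderingError(
            f"as_of {as_of} precedes extract_date {extract.extract_date}"
        )
    completeness = validate_minimum_dataset(extract)
    pending_hra_items(extract)

    stage("integrate")
    profile = merge(extract, hra)

    stage("interpret")
    interpretations = {}
    for code in CANONICAL_UNITS:
        obs = extract.latest(code)
        if obs is not None:
            interpretations[code] = interpret_value(obs, profile, as_of=as_of)
    try:
        risk_score = ten_year_chd_risk(profile, as_of=as_of)
    except InsufficientInputsError:
        risk_score = None

    stage("recommend")
    summary = build_summary(profile, ruleset, as_of)

    stage("act")
    messages = {
        rule.service_id: build_message(profile, rule, as_of)
        for rule in ruleset.services
    }
    clinician_summary = make_clinician_summary(profile, ruleset, as_of)

    return PipelineResult(
        stages=stages,
        completeness=completeness,
        profile=profile,
        interpretations=interpretations,
        risk_score=risk_score,
        summary=summary,
        messages=messages,
        clinician_summary=clinician_summary,
    )
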