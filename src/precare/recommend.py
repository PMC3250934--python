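"""Patient-facing outputs: per-service status, the general summary page, and
detailed personal messages.

The engine's verdicts become simple statements linked to visual status cues.
The summary page is a snapshot with five sections: (a) what the patient
needs now — clearly overdue services and uncontrolled chronic conditions,
(b) dates services were last received, (c) values from previous tests,
(d) categorical overviews of preventive care, and (e) missing information.
Clicking through (modeled as link tokens) reaches a detailed message whose
five domains are: a summary of the patient's information (dates, values,
risks, goals), basic information about the condition, benefits of the
service, next steps based on the individual profile, and resources to guide
those steps.  Shared-decision services additionally carry a risks block and
a how-to-decide block.

Template prose here is neutral placeholder wording with interpolation
slots; deployments are expected to replace it with professionally written
patient-education copy.
"""

from __future__ import annotations

import datetime as dt
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .errors import InsufficientInputsError
from .framingham import ten_year_chd_risk
from .interpret import Interpretation, InterpretationResult, interpret_value
from .patient import (
    CANONICAL_UNITS,
    HRA_ITEMS,
    Observation,
    PatientProfile,
    Provenance,
    Sex,
)
from .rules import (
    RESOURCE_ORDER,
    EligibilityResult,
    ResourceLink,
    RuleSet,
    ServiceRule,
    Verdict,
    detect_discrepancies,
    evaluate_eligibility,
    next_due,
)
from .translate import translate_term


class StatusState(str, Enum):
    due_now = "due_now"
    up_to_date = "up_to_date"
    discussion = "discussion"
    not_indicated = "not_indicated"
    missing_info = "missing_info"


#: 1:1 visual cue token per state; renderers map tokens to styling.
CUE_FOR_STATE: dict[StatusState, str] = {
    StatusState.due_now: "action",
    StatusState.up_to_date: "ok",
    StatusState.discussion: "info",
    StatusState.not_indicated: "na",
    StatusState.missing_info: "unknown",
}

#: The five summary-page sections, in presentation order.
SUMMARY_SECTIONS: tuple[str, ...] = (
    "needs_now",
    "service_dates",
    "prior_values",
    "category_overviews",
    "missing_information",
)

#: The five mandatory detailed-message domains, in presentation order.
MESSAGE_DOMAINS: tuple[str, ...] = (
    "patient_summary",
    "condition_info",
    "benefits",
    "next_steps",
    "guidance_resources",
)


class ServiceStatus(BaseModel):
    service_id: str
    display_name: str = ""
    state: StatusState
    last_received: Optional[dt.date] = None
    next_due: Optional[dt.date] = None
    cue: str = ""
    reasons: list[str] = []


class SummaryItem(BaseModel):
    """One needs-now entry: an overdue service or an uncontrolled condition."""

    kind: str  # "service" | "condition"
    ref: str
    label: str
    cue: str
    link: str


class TrendSeries(BaseModel):
    model_config = ConfigDict(frozen=True)

    analyte: str
    points: list[tuple[dt.date, float]]
    deltas: list[float]
    direction: str  # rising | falling | flat | single_point


class SummaryPage(BaseModel):
    patient_id: str
    as_of: dt.date
    needs_now: list[SummaryItem]
    service_dates: dict[str, dt.date]
    prior_values: dict[str, Observation]
    category_overviews: dict[str, str]
    missing_information: list[str]
    statuses: dict[str, ServiceStatus]
    discrepancies: list = []

    @property
    def sections(self) -> tuple[str, ...]:
        return SUMMARY_SECTIONS


class DetailedMessage(BaseModel):
    service_id: str
    display_name: str
    state: StatusState
    domains: dict[str, str]
    risk_block: Optional[str] = None
    decision_block: Optional[str] = None
    resources: list[ResourceLink] = []
    trend: Optional[TrendSeries] = None
    personalization_fields: list[str] = []
    clinician_linkback: str = ""
    link: str = ""


def classify_status(
    eligibility: EligibilityResult,
    rule: ServiceRule,
    profile: PatientProfile,
    as_of: dt.date,
) -> ServiceStatus:
    """Map an eligibility verdict and due date onto a patient-facing state.

    insufficient_info -> missing_info; not_indicated -> not_indicated;
    uncertain -> discussion; indicated and due on or before ``as_of`` ->
    due_now; otherwise up_to_date.  Total over every verdict/due-date
    combination.
    """
    events = profile.extract.events_for(rule.event_codes or [rule.service_id])
    last = max((e.date for e in events), default=None)
    if eligibility.verdict == Verdict.insufficient_info:
        state, due = StatusState.missing_info, None
    elif eligibility.verdict == Verdict.not_indicated:
        state, due = StatusState.not_indicated, None
    else:
        due = next_due(rule, profile, as_of)
        if eligibility.verdict == Verdict.uncertain:
            state = StatusState.discussion
        elif due is not None and due <= as_of:
            state = StatusState.due_now
        else:
            state = StatusState.up_to_date
    return ServiceStatus(
        service_id=rule.service_id,
        display_name=rule.display_name,
        state=state,
        last_received=last,
        next_due=due,
        cue=CUE_FOR_STATE[state],
        reasons=eligibility.reasons,
    )


def trend_series(labs: list[Observation], analyte: str) -> TrendSeries:
    """Date-ordered series of one analyte with successive deltas.

    Direction follows the sign of the most recent change; a single value is
    ``single_point``.  When one date carries several values the latest entry
    in input order wins, keeping points strictly date-ascending.
    """
    by_date: dict[dt.date, float] = {}
    for obs in labs:
        if obs.code == analyte:
            by_date[obs.date] = obs.value
    points = sorted(by_date.items())
    deltas = [b[1] - a[1] for a, b in zip(points, points[1:])]
    if len(points) <= 1:
        direction = "single_point"
    elif deltas[-1] > 0:
        direction = "rising"
    elif deltas[-1] < 0:
        direction = "falling"
    else:
        direction = "flat"
    return TrendSeries(analyte=analyte, points=points, deltas=deltas, direction=direction)


def select_resources(profile: PatientProfile, rule: ServiceRule) -> list[ResourceLink]:
    """Resources whose predicate matches the profile, in category order.

    Order is decision aids, risk calculators, self-management tools,
    community resources, then logistics; ties keep catalog order.
    """
    selected = []
    for link in rule.resources:
        if link.when is None:
            selected.append(link)
            continue
        fv = profile.field(link.when.field)
        if fv.known() and link.when.test(fv.value):
            selected.append(link)
    order = {cat: i for i, cat in enumerate(RESOURCE_ORDER)}
    return sorted(selected, key=lambda r: order[r.category])


def _uncontrolled_conditions(
    profile: PatientProfile, as_of: dt.date
) -> list[tuple[str, Interpretation]]:
    """Latest observation per analyte whose interpretation is above goal."""
    out = []
    for code in CANONICAL_UNITS:
        obs = profile.extract.latest(code)
        if obs is None:
            continue
        interp = interpret_value(obs, profile, as_of=as_of)
        if interp.result == InterpretationResult.above_goal:
            out.append((code, interp))
    return out


def build_summary(
    profile: PatientProfile, ruleset: RuleSet, as_of: dt.date
) -> SummaryPage:
    """Assemble the five-section general summary page.

    Every service in the rule set appears exactly once in the per-service
    statuses; needs-now lists exactly the due-now services plus conditions
    whose latest value is above its patient-specific goal.
    """
    statuses: dict[str, ServiceStatus] = {}
    for rule in ruleset.services:
        elig = evaluate_eligibility(rule, profile, as_of)
        statuses[rule.service_id] = classify_status(elig, rule, profile, as_of)

    needs_now: list[SummaryItem] = []
    for sid, status in statuses.items():
        if status.state == StatusState.due_now:
            needs_now.append(
                SummaryItem(
                    kind="service",
                    ref=sid,
                    label=f"Due now: {ruleset.get(sid).lay_name}",
                    cue=CUE_FOR_STATE[StatusState.due_now],
                    link=f"#/message/{sid}",
                )
            )
    for code, interp in _uncontrolled_conditions(profile, as_of):
        lay = translate_term(code).text
        needs_now.append(
            SummaryItem(
                kind="condition",
                ref=code,
                label=f"Above goal: {lay} (goal: {interp.goal})",
                cue="action",
                link=f"#/value/{code}",
            )
        )

    service_dates = {
        sid: s.last_received for sid, s in statuses.items() if s.last_received is not None
    }
    prior_values = {
        code: obs
        for code in CANONICAL_UNITS
        if (obs := profile.extract.latest(code)) is not None
    }

    category_overviews: dict[str, str] = {}
    for rule in ruleset.services:
        cat = rule.category.value
        state = statuses[rule.service_id].state
        rank = {"action": 4, "unknown": 3, "info": 2, "ok": 1, "na": 0}
        cue = CUE_FOR_STATE[state]
        if cat not in category_overviews or rank[cue] > rank[category_overviews[cat]]:
            category_overviews[cat] = cue

    missing = [item for item in HRA_ITEMS if not profile.field(item).known()]
    # the age-band follow-up only matters when a family history was reported
    fcc = profile.field("family_colorectal_cancer")
    if fcc.known() and fcc.value is False:
        missing = [m for m in missing if m != "family_colorectal_cancer_age_band"]
    if profile.sex == Sex.unknown:
        missing.append("sex")

    return SummaryPage(
        patient_id=profile.patient_id,
        as_of=as_of,
        needs_now=needs_now,
        service_dates=service_dates,
        prior_values=prior_values,
        category_overviews=category_overviews,
        missing_information=missing,
        statuses=statuses,
        discrepancies=[f.model_dump(mode="json") for f in detect_discrepancies(profile, ruleset, as_of)],
    )


_NEXT_STEPS = {
    StatusState.due_now: (
        "You are due now for {lay_name}. Call your doctor's office to schedule it, "
        "or ask about it at your next visit."
    ),
    StatusState.up_to_date: (
        "You are up to date on {lay_name}.{next_due_clause} Keep this page handy "
        "for your next visit."
    ),
    StatusState.discussion: (
        "Experts do not all agree on {lay_name} for someone like you. Review the "
        "information here, then talk with your doctor about what is right for you."
    ),
    StatusState.not_indicated: (
        "{display_name} is not recommended for you right now based on your age, "
        "sex, and history."
    ),
    StatusState.missing_info: (
        "We could not tell whether you need {lay_name} because some information "
        "is missing: {missing}. Please update your answers or ask your doctor."
    ),
}


def build_message(
    profile: PatientProfile, rule: ServiceRule, as_of: dt.date
) -> DetailedMessage:
    """Build the detailed personal message for one service.

    Always populates the five mandatory domains; attaches the risks and
    how-to-decide blocks when the rule is a shared-decision service; embeds
    matching resources and, when prior values exist, the value trend; and
    closes with a link back to the patient's own clinician.
    """
    elig = evaluate_eligibility(rule, profile, as_of)
    status = classify_status(elig, rule, profile, as_of)
    age = profile.age(as_of)
    personalization = ["age"]

    lines = [f"You are {age} years old."]
    if status.last_received is not None:
        lines.append(
            f"Your last {rule.lay_name} was on {status.last_received.isoformat()}."
        )
        personalization.append("last_received")
    else:
        lines.append(f"We have no record of a prior {rule.lay_name}.")
    for code in rule.analytes:
        obs = profile.extract.latest(code)
        if obs is None:
            continue
        interp = interpret_value(obs, profile, as_of=as_of)
        lay = translate_term(code).text
        goal_clause = f" Your goal: {interp.goal}." if interp.goal else ""
        lines.append(
            f"Your most recent {lay} was {obs.value:g} {obs.unit} "
            f"on {obs.date.isoformat()} ({interp.result.value.replace('_', ' ')}).{goal_clause}"
        )
        personalization.append(code)
    if rule.category.value == "heart_care":
        try:
            risk = ten_year_chd_risk(profile, as_of=as_of)
            lines.append(
                f"Your estimated chance of a heart attack in the next 10 years "
                f"is about {risk.value:g}%."
            )
            personalization.append("ten_year_chd_risk")
        except InsufficientInputsError:
            pass
    patient_summary = " ".join(lines)

    missing_fields = ", ".join(
        r.removeprefix("missing answer: ") for r in status.reasons
    )
    next_due_clause = (
        f" Your next one is due {status.next_due.isoformat()}."
        if status.next_due is not None and status.state == StatusState.up_to_date
        else ""
    )
    next_steps = _NEXT_STEPS[status.state].format(
        lay_name=rule.lay_name,
        display_name=rule.display_name,
        missing=missing_fields or "see the summary page",
        next_due_clause=next_due_clause,
    )

    resources = select_resources(profile, rule)
    if resources:
        guidance = "Tools picked for you: " + "; ".join(r.label for r in resources) + "."
    else:
        guidance = (
            "Ask your doctor's office about local programs and materials for "
            f"{rule.lay_name}."
        )

    domains = {
        "patient_summary": patient_summary,
        "condition_info": rule.condition_info
        or f"{rule.display_name}: talk with your doctor to learn more.",
        "benefits": rule.benefits
        or f"Staying current with {rule.lay_name} protects your health.",
        "next_steps": next_steps,
        "guidance_resources": guidance,
    }

    risk_block = decision_block = None
    if rule.uncertainty:
        risk_block = (
            f"Like most medical tests, {rule.lay_name} has downsides as well as "
            "benefits: false alarms, extra tests, and sometimes treatment of a "
            "problem that would never have harmed you."
        )
        decision_block = (
            "How to decide: weigh how much reassurance finding a problem early "
            "would give you against the chance of follow-up tests you might not "
            "need. Your own risks and values matter here - bring this page to "
            "your doctor and decide together."
        )

    trend = None
    for code in rule.analytes:
        series = trend_series(profile.extract.labs + profile.extract.vitals, code)
        if series.points:
            trend = series
            break

    return DetailedMessage(
        service_id=rule.service_id,
        display_name=rule.display_name,
        state=status.state,
        domains=domains,
        risk_block=risk_block,
        decision_block=decision_block,
        resources=resources,
        trend=trend,
        personalization_fields=personalization,
        clinician_linkback=(
            "Your doctor receives a copy of your updates and overdue care. "
            "Bring questions about this page to your own clinician - this tool "
            "supports, but never replaces, that conversation."
        ),
        link=f"#/message/{rule.service_id}",
    )


def actionability_audit(
    message: DetailedMessage, profile: PatientProfile, rule: ServiceRule
) -> dict[str, bool]:
    """Check the six action-promoting features of a detailed message.

    (1) explicit next steps, (2) personalized content, (3) motivational
    benefits framing, (4) matching tools and resources attached, (5)
    historical values trended when any exist, (6) link back to the
    patient's clinician.
    """
    expected_resources = select_resources(profile, rule)
    has_prior_values = any(
        profile.extract.history(code) for code in rule.analytes
    )
    return {
        "explicit_next_steps": bool(message.domains.get("next_steps")),
        "personalized": len(message.personalization_fields) >= 1,
        "motivational_benefits": bool(message.domains.get("benefits")),
        "resources_attached": [r.label for r in message.resources]
        == [r.label for r in expected_resources],
        "history_trended": (message.trend is not None) == has_prior_values,
        "clinician_linkback": bool(message.clinician_linkback),
    }
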