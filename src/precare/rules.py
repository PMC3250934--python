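"""Declarative preventive-service rules and the eligibility engine.

The registry ships 18 preventive services (cancer screening, heart care,
health behaviors, vaccines, and other services) as a declarative, versioned
YAML document.  Decision logic relies primarily on USPSTF A/B
recommendations and incorporates JNC VII (blood pressure), NCEP ATP III
(cholesterol), ADA (diabetes), ACIP (immunizations), Healthy People, and the
Dietary Guidelines where the USPSTF defers to them.  The engine itself is
guideline-agnostic: swap the rule file and the logic follows.

A rule is eligibility-by-table: an applicable-sex set, an age window, an
optional recurrence interval, optional *risk modifiers* (predicates over the
patient profile that override the window or interval — e.g. a first-degree
relative with colorectal cancer diagnosed before 60 lowers the colorectal
start age), and an optional *indication gate* (the service is indicated only
when at least one gate predicate holds, e.g. tobacco-cessation counseling
for current smokers).  Services with inconclusive or conflicting evidence
carry an uncertainty flag and come back as shared-decision items rather than
directives; organization-specific variants (the USPSTF-versus-ADA diabetes
screening split) support discrepancy detection.

When a predicate needs a profile field the patient declined to supply, the
engine does not guess: it enumerates the possible answers, and if the
verdict depends on the missing field the service is classified
``insufficient_info`` with the field named.
"""

from __future__ import annotations

import datetime as dt
import itertools
from enum import Enum
from importlib import resources as _resources
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from ._dates import add_months
from .errors import ConfigError, ContractError
from .patient import PatientProfile, Provenance, Sex

N_SERVICES = 18


class Category(str, Enum):
    cancer_screening = "cancer_screening"
    heart_care = "heart_care"
    health_behaviors = "health_behaviors"
    vaccines = "vaccines"
    other = "other"


class Verdict(str, Enum):
    indicated = "indicated"
    not_indicated = "not_indicated"
    uncertain = "uncertain"
    insufficient_info = "insufficient_info"


class Predicate(BaseModel):
    """A single test over one profile field: equals / in / ge / le."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    field: str
    op: str = "equals"
    value: object = None

    @field_validator("op")
    @classmethod
    def _op_known(cls, v: str) -> str:
        if v not in ("equals", "in", "ge", "le"):
            raise ValueError(f"unknown predicate op {v!r}")
        return v

    def test(self, value: object) -> bool:
        if self.op == "equals":
            return value == self.value
        if self.op == "in":
            return value in self.value  # type: ignore[operator]
        if self.op == "ge":
            return value is not None and value >= self.value  # type: ignore[operator]
        return value is not None and value <= self.value  # type: ignore[operator]


class RiskModifier(BaseModel):
    """Overrides applied to the rule's window/interval when ``when`` holds."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    when: Predicate
    age_min: Optional[int] = None
    age_max: Optional[int] = None
    interval_months: Optional[int] = None


class ResourceCategory(str, Enum):
    self_management = "self_management"
    decision_aid = "decision_aid"
    risk_calculator = "risk_calculator"
    community_resource = "community_resource"
    logistics = "logistics"


#: Presentation order of resource categories within a message.
RESOURCE_ORDER: tuple[ResourceCategory, ...] = (
    ResourceCategory.decision_aid,
    ResourceCategory.risk_calculator,
    ResourceCategory.self_management,
    ResourceCategory.community_resource,
    ResourceCategory.logistics,
)


class ResourceLink(BaseModel):
    """A patient-facing tool attached to a message when its predicate matches."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    label: str
    category: ResourceCategory
    when: Optional[Predicate] = None


class RuleVariant(BaseModel):
    """An alternate organization's eligibility criteria for the same service."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    source: str
    applicable_sex: list[Sex] = [Sex.female, Sex.male]
    age_min: Optional[int] = None
    age_max: Optional[int] = None
    indicated_if_any: list[Predicate] = []


class ServiceRule(BaseModel):
    """Declarative definition of one preventive service."""

    model_config = ConfigDict(extra="forbid")

    service_id: str
    display_name: str
    lay_name: str
    category: Category
    applicable_sex: list[Sex] = [Sex.female, Sex.male]
    age_min: Optional[int] = None
    age_max: Optional[int] = None
    interval_months: Optional[int] = None
    one_time: bool = False
    uncertainty: bool = False
    uncertainty_ages: Optional[tuple[int, int]] = None
    risk_modifiers: list[RiskModifier] = []
    indicated_if_any: list[Predicate] = []
    sources: list[str]
    evidence_grade: str = ""
    event_codes: list[str] = []
    analytes: list[str] = []
    alternates: list[RuleVariant] = []
    resources: list[ResourceLink] = []
    condition_info: str = ""
    benefits: str = ""

    @field_validator("sources")
    @classmethod
    def _at_least_one_source(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("every rule must name at least one source")
        return v

    @field_validator("interval_months")
    @classmethod
    def _positive_interval(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v <= 0:
            raise ValueError("interval_months must be positive")
        return v

    @model_validator(mode="after")
    def _window_ordered(self) -> "ServiceRule":
        if self.age_min is not None and self.age_max is not None:
            if self.age_min > self.age_max:
                raise ValueError("age_min must not exceed age_max")
        return self


class RuleSet(BaseModel):
    """Versioned registry of service rules."""

    model_config = ConfigDict(extra="forbid")

    version: str
    effective_date: dt.date
    services: list[ServiceRule]

    @field_validator("services")
    @classmethod
    def _unique_ids(cls, v: list[ServiceRule]) -> list[ServiceRule]:
        ids = [r.service_id for r in v]
        if len(set(ids)) != len(ids):
            raise ValueError("service_ids must be unique")
        return v

    def get(self, service_id: str) -> ServiceRule:
        for rule in self.services:
            if rule.service_id == service_id:
                return rule
        raise KeyError(service_id)


class EligibilityResult(BaseModel):
    service_id: str
    verdict: Verdict
    reasons: list[str] = []


class DiscrepancyFlag(BaseModel):
    service_id: str
    organizations: tuple[str, str]
    verdicts: tuple[Verdict, Verdict]
    explanation: str


# ---------------------------------------------------------------------------
# Registry I/O


def load_ruleset(source: Union[str, Path]) -> RuleSet:
    """Load a rule registry from a YAML file path or YAML text."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        try:
            text = Path(source).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read rule set: {exc}") from exc
    else:
        text = source
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"rule set is not valid YAML: {exc}") from exc
    try:
        return RuleSet.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"invalid rule set: {exc}") from exc


def dump_ruleset(ruleset: RuleSet) -> str:
    """Serialize a registry to canonical YAML (sorted keys, no nulls).

    The dump is deterministic, so load -> dump -> load round-trips exactly.
    """
    data = ruleset.model_dump(mode="json", exclude_none=True)
    return yaml.safe_dump(data, sort_keys=True, allow_unicode=True, width=100)


def default_ruleset() -> RuleSet:
    """The shipped registry of 18 preventive services."""
    ref = _resources.files("precare").joinpath("data/ruleset.yaml")
    return load_ruleset(ref.read_text())


# ---------------------------------------------------------------------------
# Eligibility


def _resolve(pred: Predicate, profile: PatientProfile, as_of: dt.date) -> Optional[bool]:
    """Predicate truth over the profile; None when the field is absent."""
    fv = profile.field(pred.field, as_of=as_of)
    if not fv.known():
        return None
    return pred.test(fv.value)


def _decided_verdict(
    rule: ServiceRule,
    sex: Optional[Sex],
    age: int,
    modifier_truth: list[bool],
    gate_truth: list[bool],
) -> tuple[Verdict, list[str]]:
    """Verdict under fully-known predicate assignments."""
    reasons: list[str] = []
    if Sex.female not in rule.applicable_sex or Sex.male not in rule.applicable_sex:
        if sex is None or sex not in rule.applicable_sex:
            return Verdict.not_indicated, ["sex: service does not apply"]
    age_min, age_max, interval = rule.age_min, rule.age_max, rule.interval_months
    for mod, truth in zip(rule.risk_modifiers, modifier_truth):
        if truth:
            if mod.age_min is not None:
                age_min = mod.age_min
            if mod.age_max is not None:
                age_max = mod.age_max
            if mod.interval_months is not None:
                interval = mod.interval_months
            reasons.append(f"risk modifier applied: {mod.when.field}")
    if age_min is not None and age < age_min:
        return Verdict.not_indicated, [f"age {age} below start age {age_min}"]
    if age_max is not None and age > age_max:
        return Verdict.not_indicated, [f"age {age} above stop age {age_max}"]
    if rule.indicated_if_any:
        if not any(gate_truth):
            fields = ", ".join(p.field for p in rule.indicated_if_any)
            return Verdict.not_indicated, [f"no indication present ({fields})"]
        fired = [p.field for p, t in zip(rule.indicated_if_any, gate_truth) if t]
        reasons.append(f"indicated by: {', '.join(fired)}")
    if rule.uncertainty:
        lo, hi = rule.uncertainty_ages or (age_min, age_max)
        if (lo is None or age >= lo) and (hi is None or age <= hi):
            reasons.append("guidance uncertain: shared decision")
            return Verdict.uncertain, reasons
    reasons.insert(0, f"age {age} within window")
    return Verdict.indicated, reasons


def evaluate_eligibility(
    rule: ServiceRule, profile: PatientProfile, as_of: dt.date
) -> EligibilityResult:
    """Decide whether a service is indicated for a patient on a given date.

    Returns exactly one verdict for every (rule, profile) pair.  Absent
    profile fields yield ``insufficient_info`` only when the verdict actually
    depends on them.
    """
    sex = profile.sex if profile.sex != Sex.unknown else None
    restricted = set(rule.applicable_sex) != {Sex.female, Sex.male}
    if sex is None and restricted:
        return EligibilityResult(
            service_id=rule.service_id,
            verdict=Verdict.insufficient_info,
            reasons=["sex not recorded"],
        )
    age = profile.age(as_of)

    mod_truth = [_resolve(m.when, profile, as_of) for m in rule.risk_modifiers]
    gate_truth = [_resolve(p, profile, as_of) for p in rule.indicated_if_any]

    unknown_mods = [i for i, t in enumerate(mod_truth) if t is None]
    unknown_gates = [i for i, t in enumerate(gate_truth) if t is None]

    outcomes: set[Verdict] = set()
    sample_reasons: list[str] = []
    for mod_bits in itertools.product([False, True], repeat=len(unknown_mods)):
        for gate_bits in itertools.product([False, True], repeat=len(unknown_gates)):
            mt = list(mod_truth)
            for i, b in zip(unknown_mods, mod_bits):
                mt[i] = b
            gt = list(gate_truth)
            for i, b in zip(unknown_gates, gate_bits):
                gt[i] = b
            verdict, reasons = _decided_verdict(rule, sex, age, mt, gt)  # type: ignore[arg-type]
            outcomes.add(verdict)
            sample_reasons = reasons
    if len(outcomes) == 1:
        return EligibilityResult(
            service_id=rule.service_id, verdict=outcomes.pop(), reasons=sample_reasons
        )
    missing = sorted(
        {rule.risk_modifiers[i].when.field for i in unknown_mods}
        | {rule.indicated_if_any[i].field for i in unknown_gates}
    )
    return EligibilityResult(
        service_id=rule.service_id,
        verdict=Verdict.insufficient_info,
        reasons=[f"missing answer: {f}" for f in missing],
    )


def next_due(
    rule: ServiceRule, profile: PatientProfile, as_of: dt.date
) -> Optional[dt.date]:
    """Next due date for an indicated (or shared-decision) service.

    Most recent qualifying event + interval; no prior event means due
    immediately; a one-time service already received returns None.
    Must only be called after eligibility came back indicated/uncertain.
    """
    result = evaluate_eligibility(rule, profile, as_of)
    if result.verdict not in (Verdict.indicated, Verdict.uncertain):
        raise ContractError(
            f"next_due called for {rule.service_id} with verdict {result.verdict.value}"
        )
    events = profile.extract.events_for(rule.event_codes or [rule.service_id])
    if not events:
        return as_of
    last = max(e.date for e in events)
    if rule.one_time:
        return None
    if rule.interval_months is None:
        return as_of
    interval = rule.interval_months
    for mod, truth in zip(
        rule.risk_modifiers, [_resolve(m.when, profile, as_of) for m in rule.risk_modifiers]
    ):
        if truth and mod.interval_months is not None:
            interval = mod.interval_months
    return add_months(last, interval)


def detect_discrepancies(
    profile: PatientProfile, ruleset: RuleSet, as_of: dt.date
) -> list[DiscrepancyFlag]:
    """Flag services where two organizations' criteria reach opposite verdicts.

    Only decidable verdicts (indicated / not_indicated) are compared; if
    either variant cannot be decided for this patient, no flag is emitted.
    Services with a single organization's criteria never produce flags.
    """
    flags: list[DiscrepancyFlag] = []
    for rule in ruleset.services:
        if not rule.alternates:
            continue
        primary = evaluate_eligibility(rule, profile, as_of)
        for variant in rule.alternates:
            shadow = rule.model_copy(
                update={
                    "applicable_sex": variant.applicable_sex,
                    "age_min": variant.age_min,
                    "age_max": variant.age_max,
                    "indicated_if_any": variant.indicated_if_any,
                    "risk_modifiers": [],
                    "uncertainty": False,
                    "alternates": [],
                }
            )
            secondary = evaluate_eligibility(shadow, profile, as_of)
            decidable = {Verdict.indicated, Verdict.not_indicated}
            if (
                primary.verdict in decidable
                and secondary.verdict in decidable
                and primary.verdict != secondary.verdict
            ):
                org_a = rule.sources[0]
                org_b = variant.source
                flags.append(
                    DiscrepancyFlag(
                        service_id=rule.service_id,
                        organizations=(org_a, org_b),
                        verdicts=(primary.verdict, secondary.verdict),
                        explanation=(
                            f"{org_a} finds {rule.display_name} {primary.verdict.value} "
                            f"while {org_b} finds it {secondary.verdict.value}; "
                            "discuss which recommendation fits you."
                        ),
                    )
                )
    return flags
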