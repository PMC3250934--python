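"""The record over time: scheduled re-evaluation, patient reminders, and the
clinician summary.

Each re-evaluation recomputes every service status as of a new date (the
"re-query" is modeled as re-reading the extract), appends the snapshot to an
append-only per-patient log, and reports the delta against the previous
snapshot.  Reminders are emitted only when a service *transitions into*
due-now, guarded by a suppression window (default 90 days), so re-running
the loop on unchanged state is a no-op and the total reminder count never
exceeds the number of transitions into due-now.  Reminder payloads carry
only the lay service name and a link token, no clinical values.

After each patient session a three-section summary goes to the clinician's
record: the patient's updates/corrections, their health-behavior answers,
and overdue preventive and chronic care.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from ._dates import add_months
from .errors import OrderingError
from .patient import BEHAVIOR_ITEMS, Correction, PatientProfile
from .recommend import (
    ServiceStatus,
    StatusState,
    SummaryItem,
    build_summary,
)
from .rules import RuleSet

DEFAULT_SUPPRESSION_DAYS = 90

#: The three clinician-summary sections, in order.
CLINICIAN_SECTIONS: tuple[str, ...] = (
    "updates_corrections",
    "health_behaviors",
    "overdue_care",
)


class ReminderEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    service_id: str
    trigger_date: dt.date
    channel: str = "patient_email"
    payload: str
    link: str
    suppression_key: str


class ClinicianSummary(BaseModel):
    patient_id: str
    generated_date: dt.date
    updates_corrections: list[Correction]
    health_behaviors: dict[str, object]
    overdue_care: list[SummaryItem]

    @property
    def sections(self) -> tuple[str, ...]:
        return CLINICIAN_SECTIONS


class LogEntry(BaseModel):
    as_of: dt.date
    statuses: dict[str, ServiceStatus]


class EvaluationLog(BaseModel):
    """Append-only, strictly date-increasing evaluation history."""

    patient_id: str
    entries: list[LogEntry] = []
    reminders: list[ReminderEvent] = []

    @model_validator(mode="after")
    def _strictly_increasing(self) -> "EvaluationLog":
        dates = [e.as_of for e in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("log entries must be strictly date-increasing")
        return self

    @property
    def last(self) -> Optional[LogEntry]:
        return self.entries[-1] if self.entries else None


class StatusDelta(BaseModel):
    """Services whose state changed between consecutive evaluations."""

    as_of: dt.date
    changed: dict[str, tuple[Optional[StatusState], StatusState]]

    def newly_due(self) -> list[str]:
        return [
            sid
            for sid, (_old, new) in self.changed.items()
            if new == StatusState.due_now
        ]


def reevaluate(
    profile: PatientProfile,
    ruleset: RuleSet,
    as_of: dt.date,
    log: EvaluationLog,
) -> tuple[dict[str, ServiceStatus], StatusDelta]:
    """Recompute all statuses as of a new date and append them to the log.

    Returns the fresh status map and the delta versus the previous entry
    (on first evaluation every service counts as changed from nothing).
    Raises :class:`OrderingError` if ``as_of`` does not advance the log.
    """
    if log.last is not None and as_of <= log.last.as_of:
        raise OrderingError(
            f"as_of {as_of} does not advance the log (last entry {log.last.as_of})"
        )
    summary = build_summary(profile, ruleset, as_of)
    statuses = summary.statuses
    previous = log.last.statuses if log.last is not None else {}
    changed: dict[str, tuple[Optional[StatusState], StatusState]] = {}
    for sid, status in statuses.items():
        old = previous.get(sid)
        old_state = old.state if old is not None else None
        if old_state != status.state:
            changed[sid] = (old_state, status.state)
    log.entries.append(LogEntry(as_of=as_of, statuses=statuses))
    return statuses, StatusDelta(as_of=as_of, changed=changed)


def generate_reminders(
    delta: StatusDelta,
    statuses: dict[str, ServiceStatus],
    ruleset: RuleSet,
    patient_id: str,
    log: EvaluationLog,
    suppression_days: int = DEFAULT_SUPPRESSION_DAYS,
) -> list[ReminderEvent]:
    """One reminder per service newly transitioned into due-now.

    A reminder is suppressed when one for the same (patient, service) was
    sent within the suppression window and the service has stayed due since.
    New events are appended to the log's reminder stream.
    """
    out: list[ReminderEvent] = []
    for sid in delta.newly_due():
        recent = [
            r
            for r in log.reminders
            if r.service_id == sid
            and (delta.as_of - r.trigger_date).days < suppression_days
        ]
        if recent:
            continue
        rule = ruleset.get(sid)
        event = ReminderEvent(
            patient_id=patient_id,
            service_id=sid,
            trigger_date=delta.as_of,
            payload=f"It is time for {rule.lay_name}. Sign in to learn more.",
            link=f"#/message/{sid}",
            suppression_key=f"{patient_id}:{sid}",
        )
        out.append(event)
    log.reminders.extend(out)
    return out


def make_clinician_summary(
    profile: PatientProfile,
    ruleset: RuleSet,
    as_of: dt.date,
    statuses: Optional[dict[str, ServiceStatus]] = None,
) -> ClinicianSummary:
    """Three-section summary for the clinician's record.

    Overdue care is computed from the same summary logic patients see
    (due-now services plus above-goal conditions), so the two views never
    disagree.
    """
    summary = build_summary(profile, ruleset, as_of)
    behaviors = {
        item: profile.field(item).value if profile.field(item).known() else "declined"
        for item in BEHAVIOR_ITEMS
    }
    return ClinicianSummary(
        patient_id=profile.patient_id,
        generated_date=as_of,
        updates_corrections=list(profile.corrections),
        health_behaviors=behaviors,
        overdue_care=summary.needs_now,
    )


def simulate_timeline(
    profile: PatientProfile,
    ruleset: RuleSet,
    start: dt.date,
    months: int,
    step_months: int = 3,
    suppression_days: int = DEFAULT_SUPPRESSION_DAYS,
) -> EvaluationLog:
    """Run the re-evaluation loop on a fixed profile over a span of months.

    Utility for studying reminder behavior: statuses drift as intervals
    elapse even when no new care is recorded.
    """
    log = EvaluationLog(patient_id=profile.patient_id)
    when = start
    elapsed = 0
    while elapsed <= months:
        statuses, delta = reevaluate(profile, ruleset, when, log)
        generate_reminders(
            delta, statuses, ruleset, profile.patient_id, log, suppression_days
        )
        elapsed += step_months
        when = add_months(start, elapsed)
    return log
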