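"""Plain-text / markdown renderings of the patient and clinician outputs.

The core objects are data; these helpers produce the human-readable views
the CLI writes. No HTML and no graphics — trend series stay tabular.
"""

from __future__ import annotations

from .longitudinal import ClinicianSummary
from .recommend import DetailedMessage, SummaryPage


def summary_to_markdown(summary: SummaryPage) -> str:
    lines = [f"# Your prevention summary ({summary.as_of.isoformat()})", ""]
    lines.append("## What you need now")
    if summary.needs_now:
        lines += [f"- [{item.cue}] {item.label}" for item in summary.needs_now]
    else:
        lines.append("- Nothing is overdue. Well done.")
    lines += ["", "## When you last received services"]
    for sid, date in sorted(summary.service_dates.items()):
        lines.append(f"- {sid}: {date.isoformat()}")
    lines += ["", "## Your previous test values"]
    for code, obs in sorted(summary.prior_values.items()):
        lines.append(f"- {code}: {obs.value:g} {obs.unit} ({obs.date.isoformat()})")
    lines += ["", "## How you are doing by area"]
    for cat, cue in sorted(summary.category_overviews.items()):
        lines.append(f"- {cat}: [{cue}]")
    lines += ["", "## Missing information"]
    if summary.missing_information:
        lines += [f"- {field}" for field in summary.missing_information]
    else:
        lines.append("- None")
    return "\n".join(lines) + "\n"


def message_to_markdown(message: DetailedMessage) -> str:
    lines = [f"# {message.display_name}", f"Status: {message.state.value}", ""]
    for domain, text in message.domains.items():
        lines += [f"## {domain.replace('_', ' ').title()}", text, ""]
    if message.risk_block:
        lines += ["## Risks of this service", message.risk_block, ""]
    if message.decision_block:
        lines += ["## How to decide", message.decision_block, ""]
    if message.trend is not None and message.trend.points:
        lines.append(f"## Your {message.trend.analyte} over time ({message.trend.direction})")
        lines += [f"- {d.isoformat()}: {v:g}" for d, v in message.trend.points]
        lines.append("")
    lines += ["---", message.clinician_linkback]
    return "\n".join(lines) + "\n"


def clinician_summary_to_text(summary: ClinicianSummary) -> str:
    lines = [
        f"PREVENTION SUMMARY  patient={summary.patient_id}  "
        f"date={summary.generated_date.isoformat()}",
        "",
        "UPDATES/CORRECTIONS:",
    ]
    if summary.updates_corrections:
        lines += [
            f"  {c.field}: {c.old_value!r} -> {c.new_value!r}"
            for c in summary.updates_corrections
        ]
    else:
        lines.append("  none")
    lines.append("HEALTH BEHAVIORS:")
    lines += [f"  {k}: {v}" for k, v in summary.health_behaviors.items()]
    lines.append("OVERDUE PREVENTIVE AND CHRONIC CARE:")
    if summary.overdue_care:
        lines += [f"  {item.label}" for item in summary.overdue_care]
    else:
        lines.append("  none")
    return "\n".join(lines) + "\n"
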