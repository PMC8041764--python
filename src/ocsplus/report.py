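"""Automated per-participant impairment report (the result "wheel").

The report summarises one session as a ring of ten task segments, each
impaired / spared / not_assessed / unscored, plus domain summaries,
echoing any skip reasons and administration-condition flags, and recording
the provenance of the norms used.  ``unscored`` is reserved for measures
with no scoring path in the data (figure drawings without element scores,
shown greyed).  Generation is pure: identical inputs yield byte-identical
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

from .norms import IMPAIRED, NOT_ASSESSED, WITHIN_NORMS, ImpairmentProfile
from .registry import SUBTASK_ORDER, measures_of_task
from .session import SessionLog

REPORT_SCHEMA = "ocsplus-report/1"

STATUS_GLYPH = {
    "impaired": "✗",
    "spared": "✓",
    "not_assessed": "–",
    "unscored": "·",
}


class ReportError(ValueError):
    pass


def _task_status(profile: ImpairmentProfile, task: str) -> str:
    statuses = []
    unscored = False
    for m in measures_of_task(task):
        entry = profile.measures.get(m, {"status": NOT_ASSESSED})
        if entry["status"] == NOT_ASSESSED and entry.get("reason", "").startswith("no element"):
            unscored = True
        statuses.append(entry["status"])
    if any(s == IMPAIRED for s in statuses):
        return "impaired"
    if all(s == NOT_ASSESSED for s in statuses):
        return "unscored" if unscored else "not_assessed"
    return "spared"


def generate_report(
    profile: ImpairmentProfile,
    domains: dict[str, dict],
    session: SessionLog,
) -> dict:
    """Assemble the structured report for one assessed participant."""
    if profile.participant_id != session.participant_id:
        raise ReportError(
            f"profile is for {profile.participant_id!r} but session is for "
            f"{session.participant_id!r}"
        )
    duration_ms = None
    timestamps = [e.timestamp_ms for b in session.blocks for e in b.events]
    if timestamps:
        duration_ms = max(timestamps) - min(timestamps)

    tasks = {}
    for task in SUBTASK_ORDER:
        tasks[task] = {
            "status": _task_status(profile, task),
            "measures": {
                m: profile.measures.get(m, {"status": NOT_ASSESSED})
                for m in measures_of_task(task)
            },
        }
        if task in profile.skip_reasons:
            tasks[task]["skip_reason"] = profile.skip_reasons[task]
        if task in profile.condition_flags:
            tasks[task]["condition_flags"] = profile.condition_flags[task]

    return {
        "schema": REPORT_SCHEMA,
        "participant_id": profile.participant_id,
        "session": {
            "age": session.age,
            "education_band": session.education_band,
            "sex": session.sex,
            "site": session.site,
            "session_datetime": session.session_datetime,
            "duration_ms": duration_ms,  # informational only, never classified
        },
        "norms": {"table_id": profile.table_id, "age_band": profile.age_band},
        "tasks": tasks,
        "domains": domains,
        "condition_flags": profile.condition_flags,
    }


def render_text(report: dict) -> str:
    """Plain-text rendering; statuses agree with the JSON by construction."""
    lines = [
        f"OCS-Plus report — participant {report['participant_id']}",
        f"norms: {report['norms']['table_id']} (age band {report['norms']['age_band']})",
        "",
        "Tasks:",
    ]
    for task, info in report["tasks"].items():
        glyph = STATUS_GLYPH[info["status"]]
        extra = ""
        if "skip_reason" in info:
            extra = f"  [skipped: {info['skip_reason']}]"
        if "condition_flags" in info:
            extra += f"  [flags: {', '.join(info['condition_flags'])}]"
        lines.append(f"  {glyph} {task:24s} {info['status']}{extra}")
    lines.append("")
    lines.append("Domains:")
    for name, entry in report["domains"].items():
        score = entry.get("score")
        shown = "-" if score is None else f"{score:g}"
        lines.append(f"  {name:24s} {shown:>8s}  {entry['status']}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(report, indent=2, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path
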