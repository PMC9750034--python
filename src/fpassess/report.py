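"""Per-patient assessment report: symmetry, ability, and grading combined.

A complete evaluation of one patient (rest plus the five voluntary
movements) yields 18 area symmetry indices (3 areas x 6 movements), five
ability decisions, and ten grades (5 movements x 2 sides). Partial
inputs yield partial reports with explicit missing markers rather than
zeros.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from . import faus, symmetry
from .classify import DEFAULT_MARGIN, AbilityResult, MovementClassifier
from .errors import MissingInputError, ValidationError
from .grading import GradeReport, grade_report
from .model import Session, rest_baseline
from .symmetry import ASIReport, asi_report

REPORT_SCHEMA_VERSION = 1


@dataclass
class PatientReport:
    """Assembled assessment for one patient."""

    patient_id: str
    asi: ASIReport | None = None
    ability: dict[str, AbilityResult] | None = None
    grades: GradeReport | None = None
    metadata: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        """Number of populated ASI, ability, and grade values."""
        n_asi = len(self.asi.per_area) if self.asi else 0
        n_ability = len(self.ability) if self.ability else 0
        n_grades = 2 * len(self.grades.movements) if self.grades else 0
        return {"asi": n_asi, "ability": n_ability, "grades": n_grades}


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:12]


def assess_patient(
    sessions: list[Session],
    model: MovementClassifier | None = None,
    margin: float = DEFAULT_MARGIN,
    generated_at: str | None = None,
) -> PatientReport:
    """Run all three assessment stages on one patient's sessions.

    A rest session is mandatory (it anchors both static symmetry and the
    grading baseline). Voluntary movements that are absent simply do not
    appear; the ability block is marked missing when no classifier is
    supplied. ``generated_at`` is an optional caller-supplied timestamp
    string — it is deliberately not read from the clock so that report
    generation is deterministic.
    """
    if not sessions:
        raise MissingInputError("no sessions supplied")
    patient_ids = {s.patient_id for s in sessions}
    if len(patient_ids) != 1:
        raise ValidationError(
            f"sessions span multiple patients: {sorted(patient_ids)}"
        )
    rest_sessions = [s for s in sessions if s.movement == faus.REST]
    if not rest_sessions:
        raise MissingInputError("a rest session is required for assessment")
    rest = rest_baseline(min(rest_sessions, key=lambda s: s.sample_id))
    voluntary = [s for s in sessions if s.movement != faus.REST]

    report = PatientReport(patient_id=patient_ids.pop())
    report.asi = asi_report(sessions)
    if voluntary:
        report.grades = grade_report(sessions)
        if model is not None:
            from .classify import ability_report

            report.ability = ability_report(voluntary, model, rest, margin)

    meta = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "margin": margin,
        "model": json.loads(model.describe()) if model is not None else None,
        "movements_present": sorted(
            {s.movement for s in sessions}, key=faus.MOVEMENT_INDEX.get
        ),
    }
    meta["config_hash"] = _config_hash(meta)
    if generated_at is not None:
        meta["generated_at"] = generated_at
    report.metadata = meta
    return report


def render_report(report: PatientReport, format: str = "json") -> str:
    """Serialise a report as schema'd JSON or a human-readable text sheet.

    JSON keeps full precision; the text rendering rounds symmetry
    indices to whole percent and shows missing blocks as an em dash.
    """
    if format == "json":
        return _render_json(report)
    if format == "text":
        return _render_text(report)
    raise ValidationError(f"unknown report format: {format!r}")


def _render_json(report: PatientReport) -> str:
    payload = {
        "patient_id": report.patient_id,
        "metadata": report.metadata,
        "asi": report.asi.to_dict() if report.asi else None,
        "ability": (
            {
                m: {
                    "decision": r.decision,
                    "predicted": r.predicted,
                    "confidence": r.confidence.probs,
                }
                for m, r in report.ability.items()
            }
            if report.ability
            else None
        ),
        "grades": report.grades.to_dict() if report.grades else None,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def report_from_json(document: str) -> dict:
    """Parse a rendered JSON report back into its payload dictionary."""
    return json.loads(document)


def _fmt(value: float | None) -> str:
    return "—" if value is None else f"{round(value):d}"


def _render_text(report: PatientReport) -> str:
    lines = [f"FP assessment report — patient {report.patient_id}", ""]

    lines.append("Animation symmetry indices (percent)")
    header = f"{'movement':<18}{'eyes':>6}{'brows':>7}{'mouth':>7}{'total':>7}"
    lines.append(header)
    for m in faus.MOVEMENTS:
        if report.asi and m in report.asi.per_movement_total:
            row = (
                f"{m:<18}"
                f"{_fmt(report.asi.per_area[(m, 'eyes')]):>6}"
                f"{_fmt(report.asi.per_area[(m, 'eyebrows')]):>7}"
                f"{_fmt(report.asi.per_area[(m, 'mouth')]):>7}"
                f"{_fmt(report.asi.per_movement_total[m]):>7}"
            )
        else:
            row = f"{m:<18}{'—':>6}{'—':>7}{'—':>7}{'—':>7}"
        lines.append(row)

    lines.append("")
    lines.append("Ability of performing the facial movements")
    for m in faus.VOLUNTARY_MOVEMENTS:
        if report.ability and m in report.ability:
            r = report.ability[m]
            lines.append(f"{m:<18}{r.decision:>6}   (classified as {r.predicted})")
        else:
            lines.append(f"{m:<18}{'—':>6}")

    lines.append("")
    lines.append("Facial function grades (0-10, left / right)")
    for m in faus.VOLUNTARY_MOVEMENTS:
        if report.grades and m in report.grades.movements:
            g = report.grades.movements[m]
            lines.append(f"{m:<18}{g.left_grade:>4} / {g.right_grade}")
        else:
            lines.append(f"{m:<18}{'—':>4} / —")
    return "\n".join(lines) + "\n"
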