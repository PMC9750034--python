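"""Animation Symmetry Indices (ASI) between the two facial sides.

For a mirror pair of facial animation units the symmetry index is

    ASI = (1 - |left - right|) x 100 %

clamped to [0, 100]. The clamp matters only for the eyebrow-lowerer pair,
whose units can take opposite signs so that |L - R| may exceed 1; keeping
the index in [0, 100] preserves its reading as "percent symmetry".

Three facial areas are scored: eyes (eye-closed pair), eyebrows
(eyebrow-lowerer pair) and mouth. The mouth ASI is the arithmetic mean of
four component indices — lip corner puller, lip stretcher, lip corner
depressor and cheek puff — and the per-movement total ASI is the mean of
the three area indices. Static symmetry is evaluated on the aggregated
rest frame; dynamic symmetry on the peak frame of each voluntary movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import faus
from .errors import MissingInputError, ValidationError
from .model import FAUFrame, Session, rest_baseline

MOUTH_COMPONENTS = ("lip_puller", "lip_stretcher", "lip_depressor", "cheeks")
AREAS = ("eyes", "eyebrows", "mouth")


def asi_pair(left_value: float, right_value: float) -> float:
    """Symmetry index (percent) for one left/right activation pair."""
    if not (math.isfinite(left_value) and math.isfinite(right_value)):
        raise ValidationError(
            f"non-finite activation: ({left_value}, {right_value})"
        )
    raw = (1.0 - abs(left_value - right_value)) * 100.0
    return min(100.0, max(0.0, raw))


def _pair_asi(frame: FAUFrame, feature: str) -> float:
    left, right = faus.MIRROR_PAIRS[feature]
    return asi_pair(frame.values[left], frame.values[right])


def asi_eyes(frame: FAUFrame) -> float:
    """Eye-closure symmetry from the left/right eye-closed units."""
    return _pair_asi(frame, "eyes")


def asi_eyebrows(frame: FAUFrame) -> float:
    """Eyebrow symmetry from the left/right eyebrow-lowerer units."""
    return _pair_asi(frame, "eyebrows")


def asi_mouth(frame: FAUFrame) -> tuple[float, dict[str, float]]:
    """Mouth symmetry: mean of the four mouth-component indices.

    Returns the mean and the per-component indices (lip corner puller,
    lip stretcher, lip corner depressor, cheek puff).
    """
    components = {c: _pair_asi(frame, c) for c in MOUTH_COMPONENTS}
    return sum(components.values()) / len(components), components


def total_asi(eyes: float, eyebrows: float, mouth: float) -> float:
    """Per-movement total: arithmetic mean of the three area indices."""
    return (eyes + eyebrows + mouth) / 3.0


@dataclass
class ASIReport:
    """Per-area symmetry indices for every movement of one patient.

    ``per_area`` maps ``(movement, area)`` to a percentage; a full
    six-movement evaluation yields 18 entries (3 areas x 6 movements).
    ``per_movement_total`` is the mean of the three areas, and
    ``mouth_components`` maps ``(movement, component)`` to the four mouth
    sub-indices. Missing movements are simply absent.
    """

    patient_id: str
    per_area: dict[tuple[str, str], float] = field(default_factory=dict)
    per_movement_total: dict[str, float] = field(default_factory=dict)
    mouth_components: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def movements(self) -> list[str]:
        return [m for m in faus.MOVEMENTS if m in self.per_movement_total]

    def to_dict(self) -> dict:
        """Nested JSON-ready block keyed by movement."""
        out: dict = {}
        for m in self.movements:
            out[m] = {
                "eyes": self.per_area[(m, "eyes")],
                "eyebrows": self.per_area[(m, "eyebrows")],
                "mouth": self.per_area[(m, "mouth")],
                "total": self.per_movement_total[m],
                "mouth_components": {
                    c: self.mouth_components[(m, c)] for c in MOUTH_COMPONENTS
                },
            }
        return out


def asi_frame(frame: FAUFrame) -> tuple[dict[str, float], dict[str, float], float]:
    """All area indices, mouth components, and the total for one frame."""
    mouth, components = asi_mouth(frame)
    areas = {
        "eyes": asi_eyes(frame),
        "eyebrows": asi_eyebrows(frame),
        "mouth": mouth,
    }
    return areas, components, total_asi(areas["eyes"], areas["eyebrows"], mouth)


def asi_report(sessions: list[Session]) -> ASIReport:
    """Static and dynamic symmetry report for one patient.

    The rest session is aggregated to its baseline frame (static
    symmetry); each voluntary movement is evaluated at its peak frame
    (dynamic symmetry), which requires the rest baseline for peak
    selection. Multiple samples of one movement must carry distinct
    ``sample_id`` values; the lowest sample is evaluated.
    """
    from .grading import select_peak_frame  # deferred: grading imports symmetry's peers

    if not sessions:
        raise MissingInputError("no sessions supplied")
    patient_ids = {s.patient_id for s in sessions}
    if len(patient_ids) != 1:
        raise ValidationError(
            f"sessions span multiple patients: {sorted(patient_ids)}"
        )

    by_movement: dict[str, Session] = {}
    seen: set[tuple[str, int]] = set()
    for s in sessions:
        key = (s.movement, s.sample_id)
        if key in seen:
            raise ValidationError(
                f"duplicate session for movement {s.movement!r} with "
                f"sample_id {s.sample_id}; sample_ids must disambiguate"
            )
        seen.add(key)
        current = by_movement.get(s.movement)
        if current is None or s.sample_id < current.sample_id:
            by_movement[s.movement] = s

    rest_frame: FAUFrame | None = None
    if faus.REST in by_movement:
        rest_frame = rest_baseline(by_movement[faus.REST])

    report = ASIReport(patient_id=patient_ids.pop())
    for movement in faus.MOVEMENTS:
        session = by_movement.get(movement)
        if session is None:
            continue
        if movement == faus.REST:
            frame = rest_frame
        else:
            if rest_frame is None:
                raise MissingInputError(
                    "a rest session is required to evaluate dynamic symmetry"
                )
            frame = session.frames[select_peak_frame(session, rest_frame)]
        areas, components, total = asi_frame(frame)
        for area, value in areas.items():
            report.per_area[(movement, area)] = value
        for comp, value in components.items():
            report.mouth_components[(movement, comp)] = value
        report.per_movement_total[movement] = total
    return report
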