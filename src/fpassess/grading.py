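"""Per-side 0-10 grading of the five voluntary facial movements.

Each movement engages a small set of animation units (one per facial
side, plus optionally shared units that have no side). Grading measures
the *effective delta*: the movement-minus-rest change of each engaged
unit, folded by the direction in which the unit is expected to move —
some units decrease when the movement is performed (the eyebrow lowerers
during a brow raise, the cheek-puff units during whistling), and the
direction fold makes "more movement" always positive.

The score rule awards one point per completed 0.1 of effective delta,
capped at 10 (a full-range change of 1.0), floored at 0 for absent or
paradoxical movement. Whistling combines its shared lip-pucker delta
with each side's cheek decrease by an unweighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import faus
from .errors import MissingInputError, ValidationError
from .model import FAUFrame, Session, rest_baseline

# guards binary-float artifacts such as 0.3 * 10 = 2.999...
_SCORE_EPS = 1e-9


@dataclass(frozen=True)
class MovementSpec:
    """Engaged units of one voluntary movement.

    ``per_side`` maps 'left'/'right' to (descriptor, direction) pairs;
    ``shared`` lists units without a facial side that contribute to both
    sides' grades. Direction +1 means the unit increases when the
    movement is performed, -1 that it decreases.
    """

    movement: str
    per_side: dict[str, tuple[tuple[str, int], ...]]
    shared: tuple[tuple[str, int], ...] = ()

    def all_units(self) -> tuple[tuple[str, int], ...]:
        return self.per_side["left"] + self.per_side["right"] + self.shared


MOVEMENT_SPECS: dict[str, MovementSpec] = {
    "smiling": MovementSpec(
        "smiling",
        {
            "left": (("lip_corner_puller_left", +1),),
            "right": (("lip_corner_puller_right", +1),),
        },
    ),
    "eye_closure": MovementSpec(
        "eye_closure",
        {
            "left": (("left_eye_closed", +1),),
            "right": (("right_eye_closed", +1),),
        },
    ),
    "raising_eyebrows": MovementSpec(
        "raising_eyebrows",
        {
            "left": (("left_eyebrow_lowerer", -1),),
            "right": (("right_eyebrow_lowerer", -1),),
        },
    ),
    "blowing_cheeks": MovementSpec(
        "blowing_cheeks",
        {
            "left": (("left_cheek_puff", +1),),
            "right": (("right_cheek_puff", +1),),
        },
    ),
    "whistling": MovementSpec(
        "whistling",
        {
            "left": (("left_cheek_puff", -1),),
            "right": (("right_cheek_puff", -1),),
        },
        shared=(("lip_pucker", +1),),
    ),
}


def effective_delta(
    movement_frame: FAUFrame,
    rest: FAUFrame,
    descriptor: str,
    direction: int,
) -> float:
    """direction x (movement value - rest value); positive = expected motion."""
    if descriptor not in faus.DESCRIPTOR_INDEX:
        raise ValidationError(f"unknown descriptor: {descriptor!r}")
    return direction * (movement_frame.values[descriptor] - rest.values[descriptor])


def score_from_delta(delta: float) -> int:
    """One point per completed 0.1 of effective delta, clamped to 0..10."""
    if not math.isfinite(delta):
        raise ValidationError(f"non-finite delta: {delta}")
    return min(10, int(math.floor((max(delta, 0.0) + _SCORE_EPS) * 10.0)))


def select_peak_frame(
    session: Session, rest: FAUFrame, spec: MovementSpec | None = None
) -> int:
    """Index of the frame with maximal mean effective delta.

    The mean runs over every engaged unit of the movement (both sides and
    shared units); ties go to the earliest frame so a plateau yields its
    first frame.
    """
    if spec is None:
        if session.movement not in MOVEMENT_SPECS:
            raise ValidationError(
                f"no movement spec for {session.movement!r}; expected a "
                f"voluntary movement"
            )
        spec = MOVEMENT_SPECS[session.movement]
    units = spec.all_units()
    scores = np.array(
        [
            np.mean([effective_delta(f, rest, d, sgn) for d, sgn in units])
            for f in session.frames
        ]
    )
    return int(np.argmax(scores))  # argmax returns the first maximum


@dataclass(frozen=True)
class MovementGrade:
    """Per-side grade and underlying deltas for one voluntary movement."""

    movement: str
    left_grade: int
    right_grade: int
    left_delta: float
    right_delta: float
    peak_frame_index: int


@dataclass
class GradeReport:
    """Grades for all graded movements of one patient (up to 5 x 2 sides)."""

    patient_id: str
    movements: dict[str, MovementGrade] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            m: {
                "left": g.left_grade,
                "right": g.right_grade,
                "left_delta": g.left_delta,
                "right_delta": g.right_delta,
                "peak_frame_index": g.peak_frame_index,
            }
            for m, g in self.movements.items()
        }


def _side_delta(
    frame: FAUFrame, rest: FAUFrame, spec: MovementSpec, side: str
) -> float:
    units = spec.per_side[side] + spec.shared
    return float(np.mean([effective_delta(frame, rest, d, sgn) for d, sgn in units]))


def grade_movement(session: Session, rest: FAUFrame) -> MovementGrade:
    """Grade one voluntary-movement session against the rest baseline."""
    if session.movement not in MOVEMENT_SPECS:
        raise ValidationError(
            f"cannot grade movement {session.movement!r}; expected one of "
            f"{sorted(MOVEMENT_SPECS)}"
        )
    if rest is None:
        raise MissingInputError("rest baseline frame is required for grading")
    spec = MOVEMENT_SPECS[session.movement]
    peak = select_peak_frame(session, rest, spec)
    frame = session.frames[peak]
    left = _side_delta(frame, rest, spec, "left")
    right = _side_delta(frame, rest, spec, "right")
    return MovementGrade(
        movement=session.movement,
        left_grade=score_from_delta(left),
        right_grade=score_from_delta(right),
        left_delta=left,
        right_delta=right,
        peak_frame_index=peak,
    )


def grade_report(sessions: list[Session]) -> GradeReport:
    """Grade every voluntary movement of one patient.

    Requires a rest session for the baseline. With multiple samples per
    movement (distinct ``sample_id``), the lowest sample is graded.
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
        raise MissingInputError(
            "a rest session is required to establish the grading baseline"
        )
    rest = rest_baseline(min(rest_sessions, key=lambda s: s.sample_id))
    report = GradeReport(patient_id=patient_ids.pop())
    chosen: dict[str, Session] = {}
    for s in sessions:
        if s.movement == faus.REST:
            continue
        cur = chosen.get(s.movement)
        if cur is None or s.sample_id < cur.sample_id:
            chosen[s.movement] = s
    for movement in faus.VOLUNTARY_MOVEMENTS:
        if movement in chosen:
            report.movements[movement] = grade_movement(chosen[movement], rest)
    return report
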