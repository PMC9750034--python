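"""In-memory data model: FAU frames and recording sessions.

A :class:`FAUFrame` is one time-sample of all 17 facial animation units; a
:class:`Session` is an ordered sequence of frames recorded while one
patient held the rest pose or performed one voluntary facial movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import faus
from .errors import ValidationError


@dataclass(frozen=True)
class FAUFrame:
    """One time-sample of the 17 facial animation units.

    Parameters
    ----------
    values
        Mapping of descriptor name to dimensionless activation. All 17
        descriptors must be present and within their legal range.
    timestamp
        Acquisition time in seconds, if known.
    tracking_ok
        Face-tracking confidence flag from the sensor, if recorded.
        Frames flagged ``False`` are excluded from rest-baseline
        aggregation.
    """

    values: dict[str, float]
    timestamp: float | None = None
    tracking_ok: bool | None = None

    def __post_init__(self) -> None:
        missing = set(faus.DESCRIPTORS) - set(self.values)
        if missing:
            raise ValidationError(
                f"frame is missing descriptors: {sorted(missing)}"
            )
        extra = set(self.values) - set(faus.DESCRIPTORS)
        if extra:
            raise ValidationError(f"unknown descriptors: {sorted(extra)}")
        for d, v in self.values.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite activation for {d!r}: {v}")
            lo, hi = faus.bounds(d)
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"activation for {d!r} out of range [{lo}, {hi}]: {v}"
                )

    def as_array(self) -> np.ndarray:
        """Activations as a float array in canonical descriptor order."""
        return np.array([self.values[d] for d in faus.DESCRIPTORS], dtype=float)

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        timestamp: float | None = None,
        tracking_ok: bool | None = None,
    ) -> "FAUFrame":
        if len(arr) != len(faus.DESCRIPTORS):
            raise ValidationError(f"expected 17 activations, got {len(arr)}")
        return cls(
            values={d: float(v) for d, v in zip(faus.DESCRIPTORS, arr)},
            timestamp=timestamp,
            tracking_ok=tracking_ok,
        )


@dataclass
class Session:
    """A labeled sequence of FAU frames for one patient and one movement."""

    patient_id: str
    movement: str
    frames: list[FAUFrame] = field(default_factory=list)
    affected_side: str = "unknown"
    sample_id: int = 0

    def __post_init__(self) -> None:
        if self.movement not in faus.MOVEMENTS:
            raise ValidationError(
                f"unknown movement {self.movement!r}; expected one of {faus.MOVEMENTS}"
            )
        if self.affected_side not in faus.SIDES:
            raise ValidationError(
                f"affected_side must be one of {faus.SIDES}, got {self.affected_side!r}"
            )
        if not self.frames:
            raise ValidationError("session must contain at least one frame")
        ts = [f.timestamp for f in self.frames if f.timestamp is not None]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValidationError("frame timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def as_matrix(self) -> np.ndarray:
        """Frames stacked as an (n_frames, 17) activation matrix."""
        return np.stack([f.as_array() for f in self.frames])


def rest_baseline(rest_session: Session) -> FAUFrame:
    """Aggregate a rest session into a single resting frame.

    The per-unit median over frames with good tracking (all frames when the
    flag is absent) is used: it is robust to transient tracking glitches
    and reduces to the frame itself for single-frame sessions.
    """
    if rest_session.movement != faus.REST:
        raise ValidationError(
            f"rest_baseline requires a rest session, got {rest_session.movement!r}"
        )
    frames = [f for f in rest_session.frames if f.tracking_ok is not False]
    if not frames:
        raise ValidationError("no frames with acceptable tracking in rest session")
    mat = np.stack([f.as_array() for f in frames])
    return FAUFrame.from_array(np.median(mat, axis=0))
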