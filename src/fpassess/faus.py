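"""Canonical facial animation unit (FAU) descriptors and movement labels.

The Kinect v2 SDK tracks 17 scalar facial animation units per frame, each
approximating an anatomical action unit (FACS AU). Descriptor *names* are
the canonical identifiers throughout this package; numeric "FAU<n>" codes
are deliberately avoided because they are not stable across published
listings of the same unit set.

Twelve of the units form six left/right mirror pairs (eyes, eyebrows, lip
corner puller, lip stretcher, lip corner depressor, cheek puff) used for
bilateral symmetry analysis. Activations are dimensionless: most paired
units move in [0, 1]; the eyebrow-lowerer pair and the five unpaired units
can swing negative (e.g. raising the eyebrows drives the lowerer units
below their rest value), so their legal range is [-1, 1].
"""

from __future__ import annotations

# Canonical listing order; used for CSV columns and all tie-breaking.
DESCRIPTORS: tuple[str, ...] = (
    "jaw_open",
    "lip_pucker",
    "jaw_slide_right",
    "lip_stretcher_right",
    "lip_stretcher_left",
    "lip_corner_puller_left",
    "lip_corner_puller_right",
    "lip_corner_depressor_left",
    "lip_corner_depressor_right",
    "left_cheek_puff",
    "right_cheek_puff",
    "left_eye_closed",
    "right_eye_closed",
    "right_eyebrow_lowerer",
    "left_eyebrow_lowerer",
    "lower_lip_depressor_left",
    "lower_lip_depressor_right",
)

DESCRIPTOR_INDEX: dict[str, int] = {d: i for i, d in enumerate(DESCRIPTORS)}

# Six left/right mirror pairs used in symmetry analysis, keyed by the
# facial feature they describe. Order within each tuple is (left, right).
MIRROR_PAIRS: dict[str, tuple[str, str]] = {
    "eyes": ("left_eye_closed", "right_eye_closed"),
    "eyebrows": ("left_eyebrow_lowerer", "right_eyebrow_lowerer"),
    "lip_puller": ("lip_corner_puller_left", "lip_corner_puller_right"),
    "lip_stretcher": ("lip_stretcher_left", "lip_stretcher_right"),
    "lip_depressor": ("lip_corner_depressor_left", "lip_corner_depressor_right"),
    "cheeks": ("left_cheek_puff", "right_cheek_puff"),
}

# Paired units restricted to [0, 1]; the eyebrow lowerers are excluded
# because brow raising legitimately drives them negative.
UNIT_INTERVAL_UNITS: frozenset[str] = frozenset(
    u
    for feature, pair in MIRROR_PAIRS.items()
    if feature != "eyebrows"
    for u in pair
)


def bounds(descriptor: str) -> tuple[float, float]:
    """Legal activation range for one descriptor."""
    if descriptor not in DESCRIPTOR_INDEX:
        raise KeyError(f"unknown FAU descriptor: {descriptor!r}")
    if descriptor in UNIT_INTERVAL_UNITS:
        return (0.0, 1.0)
    return (-1.0, 1.0)


def side_of(descriptor: str) -> str | None:
    """'left', 'right', or None for units without a facial side."""
    parts = descriptor.split("_")
    if "left" in parts:
        return "left"
    if "right" in parts and descriptor != "jaw_slide_right":
        return "right"
    return None


REST = "rest"
MOVEMENTS: tuple[str, ...] = (
    REST,
    "smiling",
    "eye_closure",
    "raising_eyebrows",
    "blowing_cheeks",
    "whistling",
)
VOLUNTARY_MOVEMENTS: tuple[str, ...] = MOVEMENTS[1:]
MOVEMENT_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOVEMENTS)}

SIDES: tuple[str, ...] = ("left", "right", "none", "unknown")
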