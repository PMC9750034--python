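"""Synthetic FAU session generator for normal and unilateral-palsy subjects.

Real recordings come from a depth camera tracking a patient who holds a
rest pose and then performs five voluntary movements. This generator
emulates the resulting per-frame animation-unit traces so that every
other module is testable without hardware:

* each movement activates its engaged units along a smooth rise from the
  resting value to a peak delta, reaching the peak in the final third of
  the session and holding it;
* unilateral palsy attenuates the affected side's deltas by
  ``1 - severity`` (severity 0 = healthy, 1 = complete palsy);
* a fixed per-patient resting-asymmetry offset (drawn once per patient,
  scaled by severity) models static asymmetry;
* i.i.d. Gaussian frame noise models tracking jitter, with all values
  clamped to their legal range.

Everything is reproducible from the config seed; per-patient and
per-session streams are derived with stable hashing so the same patient
always gets the same resting asymmetry regardless of which sessions are
generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import faus
from .errors import ValidationError
from .grading import MOVEMENT_SPECS, select_peak_frame
from .model import FAUFrame, Session, rest_baseline
from .relieff import DifferenceVector

#: Resting activations of a symmetric face. Cheek-puff units sit at a
#: small positive tone so that whistling's cheek *decrease* is
#: representable; all other units rest at zero.
DEFAULT_REST_VALUES: dict[str, float] = {
    d: (0.2 if d in ("left_cheek_puff", "right_cheek_puff") else 0.0)
    for d in faus.DESCRIPTORS
}

#: Peak movement-minus-rest deltas of the engaged units per movement.
#: Engaged units reach |delta| 0.8 in the direction the movement moves
#: them, except whistling's cheek decrease, which is bounded by the 0.2
#: resting cheek tone (a larger decrease would clamp at zero and break
#: the linearity of severity attenuation).
DEFAULT_ACTIVATION_PROFILES: dict[str, dict[str, float]] = {
    "smiling": {"lip_corner_puller_left": 0.8, "lip_corner_puller_right": 0.8},
    "eye_closure": {"left_eye_closed": 0.8, "right_eye_closed": 0.8},
    "raising_eyebrows": {
        "left_eyebrow_lowerer": -0.8,
        "right_eyebrow_lowerer": -0.8,
    },
    "blowing_cheeks": {"left_cheek_puff": 0.8, "right_cheek_puff": 0.8},
    "whistling": {
        "lip_pucker": 0.8,
        "left_cheek_puff": -0.2,
        "right_cheek_puff": -0.2,
    },
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic generator.

    Parameters
    ----------
    seed
        Master seed; every random stream derives from it.
    n_frames
        Frames per session (30 ≈ one second of depth-camera tracking).
    noise_sd
        Frame-level Gaussian noise, activation units.
    severity
        Palsy severity in [0, 1]; affected-side deltas scale by
        ``1 - severity``.
    affected_side
        'left', 'right', or 'none' for a healthy subject.
    rest_asymmetry_scale
        Scale (activation units) of the fixed per-patient resting
        offset applied to the affected side's paired units; the drawn
        offset is further scaled by severity.
    mirrored_blow
        Model the clinical observation that some palsy patients can
        puff the *affected* cheek but not the healthy one: attenuates
        the healthy side instead for blowing-cheeks.
    attenuate_shared
        Also attenuate side-less units (whistling's lip pucker) by
        ``1 - severity``; off by default so the healthy side's grades
        are independent of severity.
    k_samples
        Repetitions of each movement per patient.
    """

    seed: int = 0
    n_frames: int = 30
    noise_sd: float = 0.01
    severity: float = 0.0
    affected_side: str = "none"
    rest_asymmetry_scale: float = 0.05
    mirrored_blow: bool = False
    attenuate_shared: bool = False
    k_samples: int = 1
    activation_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: DEFAULT_ACTIVATION_PROFILES
    )
    rest_values: dict[str, float] = field(
        default_factory=lambda: DEFAULT_REST_VALUES
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValidationError(f"severity must be in [0, 1]: {self.severity}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0: {self.noise_sd}")
        if self.affected_side not in ("left", "right", "none"):
            raise ValidationError(
                f"affected_side must be left/right/none: {self.affected_side!r}"
            )
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


def _patient_rng(config: GeneratorConfig, patient_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, zlib.crc32(patient_id.encode())]
    )


def _session_rng(
    config: GeneratorConfig, patient_id: str, movement: str, sample_id: int
) -> np.random.Generator:
    return np.random.default_rng(
        [
            config.seed,
            zlib.crc32(patient_id.encode()),
            faus.MOVEMENT_INDEX[movement],
            sample_id,
        ]
    )


def _rest_offsets(config: GeneratorConfig, patient_id: str) -> np.ndarray:
    """Fixed per-patient resting asymmetry on the affected side's pairs."""
    offsets = np.zeros(len(faus.DESCRIPTORS))
    if config.affected_side == "none" or config.severity == 0:
        return offsets
    rng = _patient_rng(config, patient_id)
    draw = rng.normal(
        0.0, config.rest_asymmetry_scale * config.severity, len(faus.MIRROR_PAIRS)
    )
    for (feature, pair), off in zip(faus.MIRROR_PAIRS.items(), draw):
        unit = pair[0] if config.affected_side == "left" else pair[1]
        offsets[faus.DESCRIPTOR_INDEX[unit]] = off
    return offsets


def _rise(n_frames: int) -> np.ndarray:
    """Smoothstep ramp reaching 1 at two-thirds of the session, then held."""
    if n_frames == 1:
        return np.ones(1)
    t = np.arange(n_frames) / (n_frames - 1)
    x = np.minimum(t / (2.0 / 3.0), 1.0)
    return 3 * x**2 - 2 * x**3


def _attenuation(config: GeneratorConfig, movement: str, descriptor: str) -> float:
    """Severity attenuation factor for one engaged unit."""
    side = faus.side_of(descriptor)
    scale = 1.0 - config.severity
    if side is None:
        return scale if config.attenuate_shared else 1.0
    attenuated = config.affected_side
    if movement == "blowing_cheeks" and config.mirrored_blow:
        attenuated = {"left": "right", "right": "left"}.get(attenuated, "none")
    return scale if side == attenuated else 1.0


def generate_session(
    config: GeneratorConfig,
    movement: str,
    patient_id: str,
    sample_id: int = 0,
    frame_rate: float = 30.0,
) -> Session:
    """One synthetic session of the given movement (rest = no profile)."""
    if movement not in faus.MOVEMENTS:
        raise ValidationError(f"unknown movement: {movement!r}")
    rng = _session_rng(config, patient_id, movement, sample_id)
    base = np.array([config.rest_values[d] for d in faus.DESCRIPTORS])
    base = base + _rest_offsets(config, patient_id)

    deltas = np.zeros(len(faus.DESCRIPTORS))
    if movement != faus.REST:
        for d, peak in config.activation_profiles[movement].items():
            deltas[faus.DESCRIPTOR_INDEX[d]] = peak * _attenuation(
                config, movement, d
            )

    rise = _rise(config.n_frames)
    lo = np.array([faus.bounds(d)[0] for d in faus.DESCRIPTORS])
    hi = np.array([faus.bounds(d)[1] for d in faus.DESCRIPTORS])
    frames = []
    for i in range(config.n_frames):
        vals = base + deltas * rise[i]
        if config.noise_sd > 0:
            vals = vals + rng.normal(0.0, config.noise_sd, len(vals))
        vals = np.clip(vals, lo, hi)
        frames.append(
            FAUFrame.from_array(vals, timestamp=i / frame_rate, tracking_ok=True)
        )
    return Session(
        patient_id=patient_id,
        movement=movement,
        frames=frames,
        affected_side=config.affected_side,
        sample_id=sample_id,
    )


def generate_patient(config: GeneratorConfig, patient_id: str) -> list[Session]:
    """Rest plus the five voluntary movements, ``k_samples`` times each."""
    sessions = []
    for sample in range(config.k_samples):
        for movement in faus.MOVEMENTS:
            sessions.append(
                generate_session(config, movement, patient_id, sample_id=sample)
            )
    return sessions


def generate_training_dataset(
    n_per_class: int,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> list[DifferenceVector]:
    """Balanced six-class difference-vector dataset from healthy subjects.

    Each simulated subject contributes one difference vector per class:
    movement vectors are peak-frame-minus-rest-baseline differences of
    all 17 units; the rest-class vector comes from a second, independent
    rest session (pure tracking noise around zero).
    """
    if config is None:
        config = GeneratorConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    if config.severity != 0 or config.affected_side != "none":
        config = replace(config, severity=0.0, affected_side="none")

    dataset: list[DifferenceVector] = []
    for i in range(n_per_class):
        pid = f"train_{i:04d}"
        rest = rest_baseline(generate_session(config, faus.REST, pid, sample_id=0))
        for movement in faus.MOVEMENTS:
            if movement == faus.REST:
                probe = generate_session(config, faus.REST, pid, sample_id=1)
                frame = probe.frames[-1]
            else:
                session = generate_session(config, movement, pid, sample_id=0)
                frame = session.frames[select_peak_frame(session, rest)]
            diffs = {
                d: frame.values[d] - rest.values[d] for d in faus.DESCRIPTORS
            }
            dataset.append(DifferenceVector(values=diffs, label=movement))
    return dataset
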