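"""Shared fixtures and strategies for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import strategies as st

from fpassess import DESCRIPTORS, FAUFrame, GeneratorConfig, Session, generate_patient
from fpassess.faus import bounds


def make_frame(timestamp=None, tracking_ok=None, **overrides) -> FAUFrame:
    """A valid frame: all units at 0 except the named overrides."""
    values = {d: 0.0 for d in DESCRIPTORS}
    values.update(overrides)
    return FAUFrame(values=values, timestamp=timestamp, tracking_ok=tracking_ok)


def make_session(movement, frames, patient_id="p0", **kwargs) -> Session:
    return Session(patient_id=patient_id, movement=movement, frames=frames, **kwargs)


@st.composite
def frames(draw) -> FAUFrame:
    """Arbitrary valid frames (each unit within its legal range)."""
    values = {}
    for d in DESCRIPTORS:
        lo, hi = bounds(d)
        values[d] = draw(
            st.floats(lo, hi, allow_nan=False, allow_infinity=False, width=32)
        )
    return FAUFrame(values=values)


@pytest.fixture
def healthy_patient():
    """Noise-free healthy subject: six perfectly symmetric sessions."""
    cfg = GeneratorConfig(seed=11, noise_sd=0.0, severity=0.0)
    return generate_patient(cfg, "healthy")


@pytest.fixture
def palsy_patient():
    """Noise-free left-sided palsy at severity 0.7."""
    cfg = GeneratorConfig(
        seed=12,
        noise_sd=0.0,
        severity=0.7,
        affected_side="left",
        rest_asymmetry_scale=0.0,
    )
    return generate_patient(cfg, "palsy")
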