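"""Reading and writing FAU sessions as CSV or JSON.

CSV layout: one row per frame with the columns ``patient_id, movement,
sample_id, frame_index, timestamp`` followed by the 17 descriptor columns
in canonical order; two optional trailing columns (``affected_side``,
``tracking_ok``) make the write→read round trip lossless. JSON layout:
a list of session objects with an embedded ``frames`` array.
"""

from __future__ import annotations

import json
import math
import os
from typing import Iterable

import pandas as pd

from . import faus
from .errors import SchemaError, ValidationError
from .model import FAUFrame, Session

META_COLUMNS = ("patient_id", "movement", "sample_id", "frame_index", "timestamp")
OPTIONAL_COLUMNS = ("affected_side", "tracking_ok")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext == ".json":
        return "json"
    return "csv"


def read_sessions(path: str, format: str | None = None) -> list[Session]:
    """Read and validate sessions from a CSV or JSON file.

    Raises
    ------
    SchemaError
        If a required column or key is missing.
    ValidationError
        If any activation is outside its legal range (the offending row
        index is named).
    """
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    return _read_csv(path)


def write_sessions(
    sessions: Iterable[Session], path: str, format: str | None = None
) -> None:
    """Write sessions to CSV or JSON, re-readable by :func:`read_sessions`."""
    fmt = _infer_format(path, format)
    sessions = list(sessions)
    if fmt == "json":
        _write_json(sessions, path)
    else:
        _write_csv(sessions, path)


# ---------------------------------------------------------------------- CSV


def _read_csv(path: str) -> list[Session]:
    df = pd.read_csv(path)
    required = list(META_COLUMNS) + list(faus.DESCRIPTORS)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"CSV is missing required column {col!r}")
    sessions: list[Session] = []
    # preserve first-appearance order of (patient, movement, sample) groups
    keys = df[["patient_id", "movement", "sample_id"]].drop_duplicates()
    for _, (pid, movement, sample) in keys.iterrows():
        grp = df[
            (df["patient_id"] == pid)
            & (df["movement"] == movement)
            & (df["sample_id"] == sample)
        ].sort_values("frame_index")
        frames = []
        for row_idx, row in grp.iterrows():
            values = {}
            for d in faus.DESCRIPTORS:
                v = float(row[d])
                lo, hi = faus.bounds(d)
                if not math.isfinite(v) or not (lo <= v <= hi):
                    raise ValidationError(
                        f"row {row_idx}: activation for {d!r} out of range "
                        f"[{lo}, {hi}]: {v}"
                    )
                values[d] = v
            ts = row.get("timestamp")
            tracking = row.get("tracking_ok") if "tracking_ok" in grp.columns else None
            frames.append(
                FAUFrame(
                    values=values,
                    timestamp=None if pd.isna(ts) else float(ts),
                    tracking_ok=None if pd.isna(tracking) else bool(tracking),
                )
            )
        side = "unknown"
        if "affected_side" in grp.columns:
            raw = grp["affected_side"].iloc[0]
            if not pd.isna(raw):
                side = str(raw)
        sessions.append(
            Session(
                patient_id=str(pid),
                movement=str(movement),
                frames=frames,
                affected_side=side,
                sample_id=int(sample),
            )
        )
    return sessions


def _write_csv(sessions: list[Session], path: str) -> None:
    rows = []
    for s in sessions:
        for i, f in enumerate(s.frames):
            row: dict = {
                "patient_id": s.patient_id,
                "movement": s.movement,
                "sample_id": s.sample_id,
                "frame_index": i,
                "timestamp": f.timestamp,
            }
            row.update({d: f.values[d] for d in faus.DESCRIPTORS})
            row["affected_side"] = s.affected_side
            row["tracking_ok"] = f.tracking_ok
            rows.append(row)
    columns = (
        list(META_COLUMNS) + list(faus.DESCRIPTORS) + list(OPTIONAL_COLUMNS)
    )
    # default float formatting uses shortest round-tripping repr → lossless
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# --------------------------------------------------------------------- JSON


def _read_json(path: str) -> list[Session]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise SchemaError("session JSON must be a list of session objects")
    sessions = []
    for i, obj in enumerate(payload):
        for key in ("patient_id", "movement", "frames"):
            if key not in obj:
                raise SchemaError(f"session {i}: missing key {key!r}")
        frames = []
        for j, fobj in enumerate(obj["frames"]):
            if "values" not in fobj:
                raise SchemaError(f"session {i} frame {j}: missing 'values'")
            frames.append(
                FAUFrame(
                    values={k: float(v) for k, v in fobj["values"].items()},
                    timestamp=fobj.get("timestamp"),
                    tracking_ok=fobj.get("tracking_ok"),
                )
            )
        sessions.append(
            Session(
                patient_id=obj["patient_id"],
                movement=obj["movement"],
                frames=frames,
                affected_side=obj.get("affected_side", "unknown"),
                sample_id=int(obj.get("sample_id", 0)),
            )
        )
    return sessions


def _write_json(sessions: list[Session], path: str) -> None:
    payload = []
    for s in sessions:
        payload.append(
            {
                "patient_id": s.patient_id,
                "movement": s.movement,
                "affected_side": s.affected_side,
                "sample_id": s.sample_id,
                "frames": [
                    {
                        "timestamp": f.timestamp,
                        "tracking_ok": f.tracking_ok,
                        "values": {d: f.values[d] for d in faus.DESCRIPTORS},
                    }
                    for f in s.frames
                ],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
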