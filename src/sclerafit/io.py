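"""Serialization of relaxation traces (CSV + JSON sidecar, SI on load)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .poroelastic import RelaxationTrace

__all__ = ["save_trace", "load_trace"]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def save_trace(trace: RelaxationTrace, csv_path: str | Path) -> Path:
    """Write a trace as CSV (time_s, displacement_um, load_uN) + JSON sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "time_s": trace.time,
            "displacement_um": trace.displacement * 1e6,
            "load_uN": trace.load * 1e6,
        }
    ).to_csv(csv_path, index=False)
    meta = {
        "sample_id": trace.sample_id,
        "radius_m": trace.radius,
        "thickness_m": trace.nominal_thickness,
        "temperature_C": trace.temperature,
    }
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=2))
    return csv_path


def load_trace(csv_path: str | Path) -> RelaxationTrace:
    """Read a trace written by :func:`save_trace`, converting to SI."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("time_s", "displacement_um", "load_uN"):
        if col not in df.columns:
            raise ValueError(f"{csv_path}: missing column {col!r}")
    meta = {}
    sidecar = _sidecar_path(csv_path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return RelaxationTrace(
        time=df["time_s"].to_numpy(),
        displacement=df["displacement_um"].to_numpy() * 1e-6,
        load=df["load_uN"].to_numpy() * 1e-6,
        sample_id=meta.get("sample_id", csv_path.stem),
        nominal_thickness=meta.get("thickness_m"),
        radius=meta.get("radius_m"),
        temperature=meta.get("temperature_C", 37.0),
    )
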