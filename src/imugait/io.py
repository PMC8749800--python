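"""Trial-file reading and writing.

A trial is a delimited text file with a fixed header
``t_ms,Ax_g,Ay_g,Az_g,Gx_dps,Gy_dps,Gz_dps`` (optionally ``Ex_deg``,
``Ey_deg``, ``Ez_deg``) plus a JSON metadata sidecar (``<trial>.meta.json``)
carrying the sample rate, instrumented side and subject id. Values beyond
the sensor's measurement ranges (±16 g, ±2000 deg/s) are kept but flagged
as saturated. Gzip-compressed files are accepted transparently.
"""

from __future__ import annotations

import gzip
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import ACCEL_RANGE_G, GYRO_RANGE_DPS, FootMotionSignal

__all__ = ["read_trial", "write_trial", "read_events", "write_events"]

_REQUIRED = ["t_ms", "Ax_g", "Ay_g", "Az_g", "Gx_dps", "Gy_dps", "Gz_dps"]
_ANGLES = ["Ex_deg", "Ey_deg", "Ez_deg"]


def _sidecar_path(path: Path) -> Path:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    return path.with_name(Path(name).stem + ".meta.json")


def write_trial(signal: FootMotionSignal, path, subject_id: str = "synthetic",
                sep: str = ",") -> Path:
    """Write a trial CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    cols = {"t_ms": signal.t,
            "Ax_g": signal.A_x, "Ay_g": signal.A_y, "Az_g": signal.A_z,
            "Gx_dps": signal.G_x, "Gy_dps": signal.G_y, "Gz_dps": signal.G_z}
    for name, ch in zip(_ANGLES, (signal.E_x, signal.E_y, signal.E_z)):
        if ch is not None:
            cols[name] = ch
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.6g")
    meta = {"sample_rate": signal.sample_rate, "side": signal.side,
            "subject_id": subject_id}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trial(path, sample_rate: Optional[float] = None) -> FootMotionSignal:
    """Read and validate a trial file.

    The sample rate comes from the metadata sidecar when present, from
    ``sample_rate`` otherwise, and as a last resort is inferred from the
    time column. Missing columns or a non-uniform time vector raise a
    descriptive error naming the first offending row; saturated samples
    only warn.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=None, engine="python")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    side, subject = "right", None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sample_rate = meta.get("sample_rate", sample_rate)
        side = meta.get("side", side)
        subject = meta.get("subject_id")
    t = df["t_ms"].to_numpy(float)
    if t.size >= 2:
        steps = np.diff(t)
        bad = np.nonzero(~np.isclose(steps, np.median(steps),
                                     rtol=0, atol=1e-6 * max(np.median(steps), 1)))[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-uniform time step at row {int(bad[0]) + 2} "
                f"(t jumps by {steps[bad[0]]:g} ms, expected {np.median(steps):g})")
    if sample_rate is None:
        if t.size < 2:
            raise ValueError(f"{path}: cannot infer sample rate from {t.size} rows")
        sample_rate = 1000.0 / float(np.median(np.diff(t)))

    for col, limit, unit in (("Ax_g", ACCEL_RANGE_G, "g"),
                             ("Ay_g", ACCEL_RANGE_G, "g"),
                             ("Az_g", ACCEL_RANGE_G, "g"),
                             ("Gx_dps", GYRO_RANGE_DPS, "deg/s"),
                             ("Gy_dps", GYRO_RANGE_DPS, "deg/s"),
                             ("Gz_dps", GYRO_RANGE_DPS, "deg/s")):
        vals = df[col].to_numpy(float)
        n_sat = int(np.sum(np.abs(vals) > limit))
        if n_sat:
            warnings.warn(f"{path}: {n_sat} sample(s) in {col} exceed the "
                          f"±{limit:g} {unit} measurement range (saturated; "
                          f"values kept)", stacklevel=2)

    angles = {}
    for name, attr in zip(_ANGLES, ("E_x", "E_y", "E_z")):
        if name in df.columns:
            angles[attr] = df[name].to_numpy(float)
    sig = FootMotionSignal(
        sample_rate=float(sample_rate), t=t,
        A_x=df["Ax_g"].to_numpy(float), A_y=df["Ay_g"].to_numpy(float),
        A_z=df["Az_g"].to_numpy(float),
        G_x=df["Gx_dps"].to_numpy(float), G_y=df["Gy_dps"].to_numpy(float),
        G_z=df["Gz_dps"].to_numpy(float),
        side=side, **angles,
    )
    if subject is not None:
        sig.subject_id = subject  # informational attribute
    return sig


def write_events(frame: pd.DataFrame, path) -> Path:
    """Write an event (or parameter) table as CSV."""
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    """Read an event table written by :func:`write_events`."""
    return pd.read_csv(path)
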