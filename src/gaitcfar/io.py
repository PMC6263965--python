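"""Reading and writing force recordings and gait-label streams.

Interchange format is plain CSV (comma-separated, header row, UTF-8,
'.' decimal).  Sample indexing is 0-based throughout; time, when needed,
is derived as index / fs.  The canonical internal force unit is
kilogram-force (kgf); sensor voltages are converted at this boundary with
the linear calibration 0–5 V ↔ 0–200 kgf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .patterns import GaitPattern, GaitPatternSeries

__all__ = [
    "Foot",
    "Site",
    "ChannelId",
    "GCFRecording",
    "VOLTS_TO_KGF",
    "volts_to_force",
    "read_recording",
    "write_recording",
    "write_labels",
    "read_labels",
]

log = logging.getLogger(__name__)

#: linear sensor calibration: 0–5 V maps to 0–200 kgf
VOLTS_TO_KGF = 200.0 / 5.0


class Foot(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Site(str, Enum):
    HEEL = "heel"
    BALL = "ball"


@dataclass(frozen=True)
class ChannelId:
    """One of the four sensor channels: {left,right} x {heel,ball}."""

    foot: Foot
    site: Site

    def __str__(self) -> str:
        return f"{self.foot.value}_{self.site.value}"

    @classmethod
    def all(cls) -> list["ChannelId"]:
        return [cls(f, s) for f in Foot for s in Site]


@dataclass
class GCFRecording:
    """Multichannel ground-contact-force time series.

    ``channels`` maps channel name (e.g. ``"left_heel"``) to a 1-D force
    array in kgf; all channels share one length and the sampling rate
    ``fs`` (Hz).  ``subject_meta`` may carry body mass (kg) and walking
    speed (km/h).
    """

    fs: float
    channels: dict[str, np.ndarray]
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise SchemaError("recording needs at least one channel")
        clean: dict[str, np.ndarray] = {}
        lengths = set()
        for name, series in self.channels.items():
            a = np.asarray(series, dtype=float)
            if a.ndim != 1:
                raise ValueError(f"channel {name!r} must be 1-D")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            clean[name] = a
            lengths.add(a.size)
        if len(lengths) > 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        self.channels = clean

    @property
    def n_samples(self) -> int:
        return int(next(iter(self.channels.values())).size)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def volts_to_force(v):
    """Convert sensor volts to kgf: force = v * 40 (0–5 V ↔ 0–200 kgf).

    Negative voltages clamp to 0 kgf with a logged warning; works on
    scalars and arrays.
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage input contains non-finite values")
    if np.any(arr < 0):
        log.warning("negative voltage(s) clamped to 0 kgf")
        arr = np.maximum(arr, 0.0)
    out = arr * VOLTS_TO_KGF
    return float(out) if np.isscalar(v) or out.ndim == 0 else out


def read_recording(
    path,
    schema: Optional[Mapping[str, str]] = None,
    fs: float = 1000.0,
    units: str = "kgf",
) -> GCFRecording:
    """Load a force recording from CSV.

    *schema* maps channel name -> CSV column name; by default every column
    except an optional ``index``/``time`` column is taken as a channel
    named after the column.  ``units="volts"`` applies the linear sensor
    calibration on read.
    """
    path = Path(path)
    if units not in ("kgf", "volts"):
        raise ValueError(f"units must be 'kgf' or 'volts', got {units!r}")
    df = pd.read_csv(path)
    if schema is None:
        schema = {
            c: c for c in df.columns if c.lower() not in ("index", "time", "sample")
        }
    if not schema:
        raise SchemaError(f"{path}: no channel columns found")
    channels: dict[str, np.ndarray] = {}
    for name, col in schema.items():
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing column {col!r} (have {list(df.columns)})"
            )
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r}, "
                f"data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: column {col!r} is ragged/missing at data row {row}"
            )
        values = numeric.to_numpy(dtype=float)
        channels[name] = volts_to_force(values) if units == "volts" else values
    return GCFRecording(fs=fs, channels=channels)


def write_recording(path, recording: GCFRecording) -> None:
    """Write a recording as CSV with an index column plus one column per channel."""
    df = pd.DataFrame({"index": np.arange(recording.n_samples)})
    for name, series in recording.channels.items():
        df[name] = series
    df.to_csv(path, index=False, float_format="%.10g")


def write_labels(path, series: GaitPatternSeries) -> None:
    """Write a gait-label series: one row per sample, labels as stable strings."""
    if series.n_samples == 0:
        raise ValueError("cannot write an empty label series")
    df = pd.DataFrame({"index": np.arange(series.n_samples)})
    for foot in series.feet:
        df[foot] = [p.value for p in series[foot]]
    df.to_csv(path, index=False)


def read_labels(path) -> GaitPatternSeries:
    """Read a gait-label series written by :func:`write_labels`."""
    df = pd.read_csv(Path(path))
    feet = [c for c in df.columns if c != "index"]
    if not feet:
        raise SchemaError(f"{path}: no label columns found")
    try:
        labels = {
            foot: np.asarray([GaitPattern(v) for v in df[foot]], dtype=object)
            for foot in feet
        }
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return GaitPatternSeries(labels=labels)
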