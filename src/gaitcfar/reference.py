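"""Fixed-threshold comparator detectors.

Two classic threshold rules are implemented: a body-weight fraction
(5 % of body mass) and a min–max range fraction computed over the whole
trial (post hoc by construction, hence offline only).  Methods whose
internals are defined elsewhere can be supplied as plug-in status
functions and run through the same harness.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import numpy as np

from .errors import SchemaError
from .io import GCFRecording
from .patterns import PATTERN_FROM_STATUS_PAIR, GaitPatternSeries

__all__ = [
    "mariani_threshold",
    "minmax_threshold",
    "detect_with_fixed_threshold",
    "detect_with_status_fn",
    "register_plugin",
    "get_plugin",
    "PLUGIN_METHODS",
]

log = logging.getLogger(__name__)

#: channel status function: force series -> boolean on-ground array
StatusFn = Callable[[np.ndarray], np.ndarray]

#: named plug-in slots; proportional-method and self-tuning-triple-threshold
#: detectors are user-suppliable (their internals are defined in external work)
PLUGIN_METHODS: dict[str, StatusFn | None] = {"pm": None, "sttta": None}


def mariani_threshold(body_mass_kg: float) -> float:
    """Fixed threshold at 5 % of body weight, in kgf."""
    if body_mass_kg <= 0:
        raise ValueError(f"body mass must be positive, got {body_mass_kg}")
    return 0.05 * float(body_mass_kg)


def minmax_threshold(series, fraction: float = 0.05) -> float:
    """Threshold at min + fraction * (max - min) over the whole series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute a min-max threshold of an empty series")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        log.warning("constant series: min-max threshold degenerates to %g", lo)
    return lo + fraction * (hi - lo)


def _feet_with_channels(recording: GCFRecording) -> list[str]:
    feet = [
        f
        for f in ("left", "right")
        if f"{f}_heel" in recording.channels and f"{f}_ball" in recording.channels
    ]
    if not feet:
        raise SchemaError(
            f"no foot with both heel and ball channels; have {list(recording.channels)}"
        )
    return feet


def detect_with_fixed_threshold(
    recording: GCFRecording, thresholds: Mapping[str, float]
) -> GaitPatternSeries:
    """Label a recording with per-channel fixed thresholds.

    *thresholds* maps channel name -> T (kgf); on-ground iff force >= T
    (boundary inclusive, matching the adaptive detector's convention).
    The foot pattern uses the same (heel, ball) mapping as the main
    detector.
    """
    feet = _feet_with_channels(recording)
    labels = {}
    for foot in feet:
        on = {}
        for site in ("heel", "ball"):
            name = f"{foot}_{site}"
            if name not in thresholds:
                raise SchemaError(f"no threshold given for channel {name}")
            t = float(thresholds[name])
            if t <= 0:
                raise ValueError(f"threshold for {name} must be positive, got {t}")
            on[site] = recording.channels[name] >= t
        labels[foot] = np.asarray(
            [
                PATTERN_FROM_STATUS_PAIR[(int(h), int(b))]
                for h, b in zip(on["heel"], on["ball"])
            ],
            dtype=object,
        )
    return GaitPatternSeries(labels=labels)


def detect_with_status_fn(
    recording: GCFRecording, status_fn: StatusFn
) -> GaitPatternSeries:
    """Label a recording with an arbitrary per-channel status function."""
    feet = _feet_with_channels(recording)
    labels = {}
    for foot in feet:
        heel_on = np.asarray(status_fn(recording.channels[f"{foot}_heel"]), dtype=bool)
        ball_on = np.asarray(status_fn(recording.channels[f"{foot}_ball"]), dtype=bool)
        labels[foot] = np.asarray(
            [
                PATTERN_FROM_STATUS_PAIR[(int(h), int(b))]
                for h, b in zip(heel_on, ball_on)
            ],
            dtype=object,
        )
    return GaitPatternSeries(labels=labels)


def register_plugin(name: str, status_fn: StatusFn) -> None:
    """Register a user-supplied status function under a method name."""
    PLUGIN_METHODS[name] = status_fn


def get_plugin(name: str) -> StatusFn:
    fn = PLUGIN_METHODS.get(name)
    if fn is None:
        raise NotImplementedError(
            f"method {name!r} is a plug-in slot; register a status function with "
            "register_plugin() — its internals are defined in external work"
        )
    return fn
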