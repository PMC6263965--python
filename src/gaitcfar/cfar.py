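"""Constant-false-alarm-rate threshold from unstable-area force samples.

The off-ground portion of a low-pass-filtered ground-contact-force signal
behaves like the magnitude of isotropic Gaussian noise, i.e. it is
Rayleigh distributed.  For Rayleigh(sigma) noise the exceedance
probability of a threshold T is exp(-T^2 / (2 sigma^2)), so fixing a
false-alarm probability p gives the closed-form threshold

    T = sigma * sqrt(-2 ln p).

The scale sigma is estimated from the unstable-interval samples through
the Rayleigh mean identity E[x] = sigma * sqrt(pi/2).  A new threshold is
computed each time an unstable interval ends in a fresh ascent (the start
of the next loading phase), and applies to the following gait cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError

__all__ = [
    "PfMode",
    "CfarParams",
    "ThresholdRecord",
    "ContactStatus",
    "estimate_sigma",
    "resolve_pf",
    "compute_threshold",
    "finalize_unstable",
    "status_division",
    "SQRT_2_OVER_PI",
]

log = logging.getLogger(__name__)

SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


class PfMode(str, Enum):
    """How the user-facing false-alarm parameter maps to a probability."""

    PROBABILITY = "probability"  # p = value
    INVERSE_GAIN = "inverse_gain"  # p = 1 / value
    NEG_LOG = "neg_log"  # p = exp(-value)
    PERCENT = "percent"  # p = value / 100


class ContactStatus(str, Enum):
    """Thresholded on/off-ground decision for one sensor channel."""

    ON_GROUND = "ON_GROUND"
    OFF_GROUND = "OFF_GROUND"
    UNDEFINED = "UNDEFINED"  # no threshold available yet (warm-up)


@dataclass(frozen=True)
class CfarParams:
    """False-alarm configuration of the adaptive threshold.

    ``pf_value`` with the default ``inverse_gain`` mode reads as a gain:
    the effective false-alarm probability is 1/pf_value (default 20.5,
    i.e. p ≈ 0.0488).  ``trim_tail`` drops that many trailing samples from
    each unstable buffer before estimation, guarding against contamination
    by the new ascent that the window detector reports with a lag (default
    38, the default ascending-window size).  Buffers shorter than
    ``min_unstable_samples`` after trimming do not update the threshold;
    the previous one is reused (short unstable intervals occur at fast
    cadence).
    """

    pf_value: float = 20.5
    pf_mode: PfMode | str = PfMode.INVERSE_GAIN
    min_unstable_samples: int = 20
    trim_tail: int = 38

    def __post_init__(self) -> None:
        object.__setattr__(self, "pf_mode", PfMode(self.pf_mode))
        if not np.isfinite(self.pf_value):
            raise ConfigError("pf_value must be finite")
        if self.min_unstable_samples < 1:
            raise ConfigError("min_unstable_samples must be >= 1")
        if self.trim_tail < 0:
            raise ConfigError("trim_tail must be >= 0")
        resolve_pf(self)  # range check for the chosen mode


@dataclass(frozen=True)
class ThresholdRecord:
    """One adaptive-threshold computation and its provenance."""

    interval: tuple[int, int]  # half-open sample-index range of contributing samples
    x_bar: float  # mean force of contributing samples (kgf)
    sigma: float  # Rayleigh scale estimate (kgf)
    threshold: float  # detection threshold T (kgf)
    computed_at: int  # sample index of the ascent-declared event

    def __post_init__(self) -> None:
        if self.interval[1] <= self.interval[0]:
            raise ValueError("interval must be non-empty")
        if self.x_bar < 0 or self.sigma < 0 or self.threshold < 0:
            raise ValueError("x_bar, sigma and threshold must be non-negative")


def estimate_sigma(values: Sequence[float]) -> float:
    """Rayleigh scale from the sample mean: sigma = mean * sqrt(2/pi)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot estimate sigma from an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("sigma estimation requires finite values")
    if np.any(x < 0):
        raise ValueError("sigma estimation requires non-negative forces")
    return float(x.mean()) * SQRT_2_OVER_PI


def resolve_pf(params: CfarParams) -> float:
    """Effective false-alarm probability p in (0, 1) for *params*."""
    v = params.pf_value
    mode = PfMode(params.pf_mode)
    if mode is PfMode.PROBABILITY:
        if not 0.0 < v < 1.0:
            raise ConfigError(f"probability mode needs 0 < pf_value < 1, got {v}")
        return float(v)
    if mode is PfMode.INVERSE_GAIN:
        if v <= 1.0:
            raise ConfigError(f"inverse_gain mode needs pf_value > 1, got {v}")
        return 1.0 / float(v)
    if mode is PfMode.NEG_LOG:
        if v <= 0.0:
            raise ConfigError(f"neg_log mode needs pf_value > 0, got {v}")
        return math.exp(-float(v))
    if not 0.0 < v < 100.0:
        raise ConfigError(f"percent mode needs 0 < pf_value < 100, got {v}")
    return float(v) / 100.0


def compute_threshold(sigma: float, p: float) -> float:
    """CFAR threshold T = sigma * sqrt(-2 ln p).

    For X ~ Rayleigh(sigma), P(X > T) = p exactly.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"false-alarm probability must lie in (0, 1), got {p}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return float(sigma) * math.sqrt(-2.0 * math.log(p))


def finalize_unstable(
    indices: Sequence[int],
    values: Sequence[float],
    params: CfarParams,
    previous: Optional[ThresholdRecord],
    computed_at: int,
) -> Optional[ThresholdRecord]:
    """Turn a finished unstable buffer into a new :class:`ThresholdRecord`.

    Drops the trailing ``trim_tail`` samples (they already belong to the
    new ascent the window detector reports late).  If fewer than
    ``min_unstable_samples`` remain, the previous record is returned
    unchanged (possibly ``None``) with a logged warning.
    """
    if len(indices) != len(values):
        raise ValueError("indices and values must have equal length")
    n_keep = len(values) - params.trim_tail
    if n_keep < params.min_unstable_samples:
        log.warning(
            "unstable buffer too short (%d samples after trimming %d); "
            "reusing previous threshold",
            max(n_keep, 0),
            params.trim_tail,
        )
        return previous
    kept_values = np.asarray(values[:n_keep], dtype=float)
    kept_indices = indices[:n_keep]
    x_bar = float(kept_values.mean())
    sigma = estimate_sigma(kept_values)
    p = resolve_pf(params)
    return ThresholdRecord(
        interval=(int(kept_indices[0]), int(kept_indices[-1]) + 1),
        x_bar=x_bar,
        sigma=sigma,
        threshold=compute_threshold(sigma, p),
        computed_at=int(computed_at),
    )


def status_division(force: float, record: Optional[ThresholdRecord]) -> ContactStatus:
    """On/off-ground decision: on-ground iff force >= T (boundary inclusive)."""
    if not np.isfinite(force):
        raise ValueError(f"force must be finite, got {force!r}")
    if record is None:
        return ContactStatus.UNDEFINED
    return ContactStatus.ON_GROUND if force >= record.threshold else ContactStatus.OFF_GROUND
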