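"""Optional Butterworth low-pass preprocessing of force channels.

The default is a causal second-order filter with a 200 Hz cut-off — high
enough to leave the off-ground noise-magnitude distribution intact, which
the CFAR stage depends on.  Filtering is initialised at the steady state
of the first sample so a constant input passes through unchanged (no
start-up transient).  A zero-phase (forward-backward) mode exists for
offline reproduction only, since it is non-causal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

from .errors import ConfigError

__all__ = ["FilterMode", "FilterConfig", "lowpass", "StreamingLowpass"]

log = logging.getLogger(__name__)


class FilterMode(str, Enum):
    CAUSAL = "causal"
    ZERO_PHASE_OFFLINE = "zero_phase_offline"
    OFF = "off"


@dataclass(frozen=True)
class FilterConfig:
    """Low-pass configuration: cut-off (Hz), order, and filtering mode."""

    cutoff_hz: float = 200.0
    order: int = 2
    mode: FilterMode | str = FilterMode.CAUSAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", FilterMode(self.mode))
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff_hz must be positive")
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")

    def validate_for(self, fs: float) -> None:
        if self.mode is FilterMode.OFF:
            return
        if not self.cutoff_hz < fs / 2:
            raise ConfigError(
                f"cutoff {self.cutoff_hz} Hz must be below the Nyquist frequency "
                f"{fs / 2} Hz (fs={fs})"
            )
        if self.cutoff_hz < 50.0:
            log.warning(
                "cut-off %.1f Hz is aggressive; heavy filtering distorts the "
                "off-ground noise distribution the adaptive threshold assumes",
                self.cutoff_hz,
            )


def _design(cfg: FilterConfig, fs: float) -> np.ndarray:
    cfg.validate_for(fs)
    return sps.butter(cfg.order, cfg.cutoff_hz, btype="low", fs=fs, output="sos")


def lowpass(series, fs: float, cfg: FilterConfig) -> np.ndarray:
    """Filter *series* according to *cfg*; same length as the input.

    ``mode=off`` returns the input untouched.  ``mode=causal`` uses a
    single forward pass with steady-state initial conditions; this is the
    streaming-compatible path.  ``mode=zero_phase_offline`` runs
    forward-backward filtering (zero phase lag, offline only).
    """
    x = np.asarray(series, dtype=float)
    if cfg.mode is FilterMode.OFF:
        return x
    if x.size < 3 * cfg.order:
        raise ValueError(f"series too short to filter (need >= {3 * cfg.order} samples)")
    sos = _design(cfg, fs)
    if cfg.mode is FilterMode.CAUSAL:
        zi = sps.sosfilt_zi(sos) * x[0]
        y, _ = sps.sosfilt(sos, x, zi=zi)
        return y
    return sps.sosfiltfilt(sos, x)


class StreamingLowpass:
    """Sample-by-sample causal Butterworth filter with carried state.

    Chunked or per-sample processing produces bit-identical output to one
    batch :func:`lowpass` call in causal mode, so a streaming pipeline and
    an offline run agree exactly.
    """

    def __init__(self, fs: float, cfg: FilterConfig) -> None:
        if cfg.mode is not FilterMode.CAUSAL:
            raise ConfigError("StreamingLowpass requires mode='causal'")
        self._sos = _design(cfg, fs)
        self._zi: np.ndarray | None = None

    def process(self, chunk) -> np.ndarray:
        x = np.atleast_1d(np.asarray(chunk, dtype=float))
        if self._zi is None:
            self._zi = sps.sosfilt_zi(self._sos) * x[0]
        y, self._zi = sps.sosfilt(self._sos, x, zi=self._zi)
        return y

    def process_sample(self, value: float) -> float:
        return float(self.process([value])[0])
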