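"""Run-length sliding windows over the sign of the force first difference.

Two fixed-length binary windows track how long the ground-contact-force
signal has been rising or falling.  Each incoming sample contributes the
sign of its first difference: a positive difference pushes a 1 into the
ascending window and a 0 into the descending window, a negative difference
does the converse, and a zero difference pushes 0 into both.  When the
one-count of a window exceeds its limit the signal is declared to be in a
continuous ascending (or descending) area; otherwise the sample lies in the
unstable area, where the signal fluctuates around the off-ground noise
floor.  The unstable area is what the CFAR threshold estimator feeds on.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, InternalConsistencyError

__all__ = [
    "AreaLabel",
    "WindowParams",
    "WindowState",
    "init_state",
    "update",
    "classify",
    "label_series",
    "area_label_codes",
    "CODE_TO_LABEL",
]


class AreaLabel(str, Enum):
    """Per-sample segmentation label of the force signal."""

    CONTINUOUS_ASCENDING = "CONTINUOUS_ASCENDING"
    CONTINUOUS_DESCENDING = "CONTINUOUS_DESCENDING"
    UNSTABLE = "UNSTABLE"


#: integer codes used by the vectorised labeller
CODE_UNSTABLE, CODE_ASC, CODE_DESC = 0, 1, 2
CODE_TO_LABEL = {
    CODE_UNSTABLE: AreaLabel.UNSTABLE,
    CODE_ASC: AreaLabel.CONTINUOUS_ASCENDING,
    CODE_DESC: AreaLabel.CONTINUOUS_DESCENDING,
}


@dataclass(frozen=True)
class WindowParams:
    """Sizes and one-count limits of the ascending/descending windows.

    Defaults are the optimised values found by exhaustive search against
    off-ground force data: ascending window of 38 samples with limit 35,
    descending window of 40 samples with limit 36.
    """

    asc_size: int = 38
    asc_limit: int = 35
    desc_size: int = 40
    desc_limit: int = 36

    def __post_init__(self) -> None:
        for name in ("asc_size", "asc_limit", "desc_size", "desc_limit"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ConfigError(f"window parameter {name} must be an integer, got {v!r}")
        if not 0 < self.asc_limit < self.asc_size:
            raise ConfigError(
                f"need 0 < asc_limit < asc_size, got {self.asc_limit}/{self.asc_size}"
            )
        if not 0 < self.desc_limit < self.desc_size:
            raise ConfigError(
                f"need 0 < desc_limit < desc_size, got {self.desc_limit}/{self.desc_size}"
            )
        # Overlap feasibility: an ascending count > asc_limit and a
        # descending count > desc_limit can co-occur on some sign stream
        # iff asc_limit + desc_limit + 2 <= max(asc_size, desc_size)
        # (pack the pluses into the shorter window's most recent slots and
        # fill the rest of the longer window with minuses).
        if self.asc_limit + self.desc_limit + 2 <= max(self.asc_size, self.desc_size):
            raise ConfigError(
                "window parameters admit simultaneous continuous-ascending and "
                "continuous-descending classification; require "
                "asc_limit + desc_limit + 2 > max(asc_size, desc_size)"
            )


class WindowState:
    """Mutable state of the two sliding windows.

    Both windows are kept at full length at all times (initially all
    zeros), so each update evicts the oldest bit and appends the newest;
    one-counts are maintained incrementally in O(1).
    """

    __slots__ = ("asc_bits", "desc_bits", "asc_count", "desc_count", "prev_force")

    def __init__(self, params: WindowParams) -> None:
        self.asc_bits: deque[int] = deque([0] * params.asc_size, maxlen=params.asc_size)
        self.desc_bits: deque[int] = deque([0] * params.desc_size, maxlen=params.desc_size)
        self.asc_count: int = 0
        self.desc_count: int = 0
        self.prev_force: float | None = None


def init_state(params: WindowParams) -> WindowState:
    """Return a fresh all-zero window state for *params*."""
    return WindowState(params)


def update(state: WindowState, force: float) -> WindowState:
    """Push one force sample into *state* (in place) and return it.

    The first sample only records ``prev_force``; every later sample shifts
    both windows by one, appending (1, 0) on a rise, (0, 1) on a fall and
    (0, 0) on a tie.
    """
    if not np.isfinite(force):
        raise ValueError(f"force must be finite, got {force!r}")
    force = float(force)
    if state.prev_force is None:
        state.prev_force = force
        return state
    diff = force - state.prev_force
    state.prev_force = force
    a = 1 if diff > 0 else 0
    d = 1 if diff < 0 else 0
    state.asc_count += a - state.asc_bits[0]
    state.asc_bits.append(a)  # maxlen deque evicts the leftmost bit
    state.desc_count += d - state.desc_bits[0]
    state.desc_bits.append(d)
    return state


def classify(state: WindowState, params: WindowParams) -> AreaLabel:
    """Area label for the current window state (strict count > limit)."""
    asc = state.asc_count > params.asc_limit
    desc = state.desc_count > params.desc_limit
    if asc and desc:  # unreachable once WindowParams validated
        raise InternalConsistencyError(
            "both windows exceed their limits; window parameters were not validated"
        )
    if asc:
        return AreaLabel.CONTINUOUS_ASCENDING
    if desc:
        return AreaLabel.CONTINUOUS_DESCENDING
    return AreaLabel.UNSTABLE


def label_series(
    series: Iterable[float], params: WindowParams
) -> tuple[list[AreaLabel], list[tuple[int, AreaLabel]]]:
    """Label every sample of *series* by streaming the window detector.

    Returns ``(labels, events)`` where *events* lists ``(index, new_label)``
    for every label transition.  The first sample has no difference and is
    labelled UNSTABLE by convention.
    """
    values = list(series)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to label a series")
    state = init_state(params)
    labels: list[AreaLabel] = []
    events: list[tuple[int, AreaLabel]] = []
    for i, f in enumerate(values):
        update(state, f)
        lab = classify(state, params)
        if i > 0 and lab is not labels[-1]:
            events.append((i, lab))
        labels.append(lab)
    return labels, events


def area_label_codes(series: Sequence[float], params: WindowParams) -> np.ndarray:
    """Vectorised equivalent of :func:`label_series`, as int8 codes.

    Computes, for every sample i >= 1, the number of positive (negative)
    differences among the last ``asc_size`` (``desc_size``) differences via
    cumulative sums — exactly the one-counts the streaming windows hold,
    since the windows start zero-filled.  Used by the parameter-search
    module where many long series must be labelled; property-tested equal
    to the streaming path.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    d = np.diff(x)
    pos = np.concatenate(([0], np.cumsum(d > 0)))
    neg = np.concatenate(([0], np.cumsum(d < 0)))
    idx = np.arange(1, x.size)
    ca = pos[idx] - pos[np.maximum(idx - params.asc_size, 0)]
    cd = neg[idx] - neg[np.maximum(idx - params.desc_size, 0)]
    codes = np.zeros(x.size, dtype=np.int8)
    codes[idx[ca > params.asc_limit]] = CODE_ASC
    codes[idx[cd > params.desc_limit]] = CODE_DESC
    return codes
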