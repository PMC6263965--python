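"""Streaming gait-phase state machine over heel and ball force channels.

Per foot, each sample passes through: window update -> area label ->
threshold maintenance -> contact status -> gait pattern.  Work per sample
is amortised O(1), so the detector is usable in a real-time loop.

Two reconciliations between the instantaneous window counts and the
interval-level detection rule are applied (both documented in the methods
note):

* **Contact region bridging** — around every force peak the one-counts
  transiently drop between the end of the ascent and the start of the
  descent, which would momentarily label loaded samples "unstable".  The
  channel therefore stays in its contact region from the sample where the
  ascent is declared until the descent hands back to the noise floor (or
  until an unstable gap outlasts the largest window, a safety valve for
  non-gait signals).

* **Status latch** — within one contact region, once the force has
  crossed below the threshold it stays off-ground until the region ends.
  This mirrors the single on/off crossing pair a loading/unloading hump
  geometrically has, and prevents post-descent noise exceedances (expected
  at the configured false-alarm rate) from re-asserting ground contact
  while the window counts decay.

The raw per-sample area labels remain available in the channel traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .cfar import (
    CfarParams,
    ContactStatus,
    ThresholdRecord,
    finalize_unstable,
    status_division,
)
from .errors import ConfigError, SchemaError
from .filters import FilterConfig, FilterMode, lowpass
from .io import GCFRecording
from .patterns import PATTERN_FROM_STATUS_PAIR, GaitPattern, GaitPatternSeries
from .windows import AreaLabel, WindowParams, classify, init_state, update

__all__ = [
    "RuleMode",
    "DetectorParams",
    "ChannelTrace",
    "ChannelDetector",
    "FootDetector",
    "classify_pattern",
    "run_offline",
]


class RuleMode(str, Enum):
    """How the both-channels-unstable case resolves.

    ``discussion_consistent`` (default): unstable means off-ground, so
    both-unstable is Swing.  ``table1_literal`` keeps the printed rule
    table verbatim, where both-unstable is Full-Stance.
    """

    DISCUSSION_CONSISTENT = "discussion_consistent"
    TABLE1_LITERAL = "table1_literal"


@dataclass(frozen=True)
class DetectorParams:
    """Complete configuration of the gait detector."""

    windows: WindowParams = field(default_factory=WindowParams)
    cfar: CfarParams = field(default_factory=CfarParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    rule_mode: RuleMode | str = RuleMode.DISCUSSION_CONSISTENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule_mode", RuleMode(self.rule_mode))


@dataclass
class ChannelTrace:
    """Per-sample diagnostics of one channel run.

    ``areas`` are the rule-level (contact-region) labels the pattern rule
    saw; ``raw_areas`` the instantaneous window classifications;
    ``statuses`` the (latched) threshold decisions; ``thresholds`` every
    adaptive threshold computed, in order.
    """

    areas: list[AreaLabel] = field(default_factory=list)
    raw_areas: list[AreaLabel] = field(default_factory=list)
    statuses: list[ContactStatus] = field(default_factory=list)
    thresholds: list[ThresholdRecord] = field(default_factory=list)


def classify_pattern(
    heel_area: AreaLabel,
    heel_status: ContactStatus,
    ball_area: AreaLabel,
    ball_status: ContactStatus,
    mode: RuleMode | str = RuleMode.DISCUSSION_CONSISTENT,
) -> GaitPattern:
    """Combine the two channels' area labels and statuses into a gait phase.

    A channel in the unstable area counts as off-ground regardless of its
    thresholded status; in continuous areas the thresholded status is
    used.  Any channel whose effective status is undefined (continuous
    area, no threshold yet) makes the pattern UNDEFINED.  In
    ``table1_literal`` mode the both-unstable case maps to Full-Stance
    instead of Swing.
    """
    mode = RuleMode(mode)
    if (
        mode is RuleMode.TABLE1_LITERAL
        and heel_area is AreaLabel.UNSTABLE
        and ball_area is AreaLabel.UNSTABLE
    ):
        return GaitPattern.FULL_STANCE

    def effective(area: AreaLabel, status: ContactStatus) -> Optional[int]:
        if area is AreaLabel.UNSTABLE:
            return 0
        if status is ContactStatus.UNDEFINED:
            return None
        return 1 if status is ContactStatus.ON_GROUND else 0

    heel = effective(heel_area, heel_status)
    ball = effective(ball_area, ball_status)
    if heel is None or ball is None:
        return GaitPattern.UNDEFINED
    return PATTERN_FROM_STATUS_PAIR[(heel, ball)]


class ChannelDetector:
    """Streaming detector state for one sensor channel."""

    def __init__(self, params: DetectorParams) -> None:
        self.params = params
        self.window = init_state(params.windows)
        self.record: Optional[ThresholdRecord] = None
        self.thresholds: list[ThresholdRecord] = []
        self._raw_prev = AreaLabel.UNSTABLE
        self._region_unstable = True
        self._last_continuous: Optional[AreaLabel] = None
        self._gap_run = 0
        self._gap_tolerance = max(params.windows.asc_size, params.windows.desc_size)
        self._latched_off = False
        self._was_on = False
        self._buf_indices: list[int] = []
        self._buf_values: list[float] = []
        self._i = -1

    def step(self, force: float) -> tuple[AreaLabel, ContactStatus]:
        """Process one sample; returns (rule-level area, contact status)."""
        self._i += 1
        # contact forces are physically non-negative; causal-filter
        # undershoot below zero is clipped so the Rayleigh estimator's
        # domain holds
        force = max(float(force), 0.0)
        update(self.window, force)
        raw = classify(self.window, self.params.windows)
        prev = self._raw_prev

        # Unstable-buffer maintenance: a fresh unstable interval starts
        # whenever the raw label re-enters UNSTABLE; the buffer is sealed
        # into a threshold when the interval ends in a new ascent.
        if raw is AreaLabel.UNSTABLE:
            if prev is not AreaLabel.UNSTABLE:
                self._buf_indices = []
                self._buf_values = []
            self._buf_indices.append(self._i)
            self._buf_values.append(force)
        elif prev is AreaLabel.UNSTABLE and raw is AreaLabel.CONTINUOUS_ASCENDING:
            rec = finalize_unstable(
                self._buf_indices,
                self._buf_values,
                self.params.cfar,
                self.record,
                computed_at=self._i,
            )
            if rec is not None and rec is not self.record:
                self.thresholds.append(rec)
            self.record = rec

        # Contact-region state machine (see module docstring).
        if raw is not AreaLabel.UNSTABLE:
            if self._region_unstable:  # region (re)start: clear the latch
                self._latched_off = False
                self._was_on = False
            self._region_unstable = False
            self._last_continuous = raw
            self._gap_run = 0
        elif not self._region_unstable:
            if self._last_continuous is AreaLabel.CONTINUOUS_DESCENDING:
                self._region_unstable = True
            else:
                self._gap_run += 1
                if self._gap_run > self._gap_tolerance:
                    self._region_unstable = True
        self._raw_prev = raw

        status = status_division(force, self.record)
        if not self._region_unstable and status is not ContactStatus.UNDEFINED:
            on = status is ContactStatus.ON_GROUND
            if self._latched_off:
                on = False
            elif self._was_on and not on:
                self._latched_off = True
            self._was_on = on
            status = ContactStatus.ON_GROUND if on else ContactStatus.OFF_GROUND

        area = (
            AreaLabel.UNSTABLE
            if self._region_unstable
            else self._last_continuous  # type: ignore[return-value]
        )
        return area, status

    @property
    def raw_area(self) -> AreaLabel:
        return self._raw_prev


class FootDetector:
    """Two-channel (heel + ball) streaming gait-phase detector for one foot."""

    def __init__(self, params: Optional[DetectorParams] = None) -> None:
        self.params = params or DetectorParams()
        self.heel = ChannelDetector(self.params)
        self.ball = ChannelDetector(self.params)

    def step(self, heel_force: float, ball_force: float) -> GaitPattern:
        """Consume one sample pair and emit the current gait pattern."""
        heel_area, heel_status = self.heel.step(heel_force)
        ball_area, ball_status = self.ball.step(ball_force)
        return classify_pattern(
            heel_area, heel_status, ball_area, ball_status, self.params.rule_mode
        )


def _prefiltered(recording: GCFRecording, cfg: FilterConfig) -> dict[str, np.ndarray]:
    if cfg.mode is FilterMode.OFF:
        return dict(recording.channels)
    return {
        name: lowpass(series, recording.fs, cfg)
        for name, series in recording.channels.items()
    }


def run_offline(
    recording: GCFRecording,
    params: Optional[DetectorParams] = None,
    feet: Optional[list[str]] = None,
) -> tuple[GaitPatternSeries, dict[str, dict[str, ChannelTrace]]]:
    """Run the detector over a whole recording.

    Channels must be named ``{foot}_heel`` / ``{foot}_ball``.  *feet*
    defaults to every foot with both channels present.  Filtering follows
    ``params.filter`` (applied causally in one pass, identical to
    per-sample streaming).  The emitted labels equal feeding the filtered
    samples one-by-one through :class:`FootDetector` — the loop below *is*
    that stream.

    Returns the label series and per-foot traces
    ``{foot: {"heel": ChannelTrace, "ball": ChannelTrace}}``.
    """
    params = params or DetectorParams()
    if recording.n_samples == 0:
        raise SchemaError("recording has no samples")
    if feet is None:
        feet = [
            f
            for f in ("left", "right")
            if f"{f}_heel" in recording.channels and f"{f}_ball" in recording.channels
        ]
        if not feet:
            raise SchemaError(
                "no foot with both heel and ball channels found; channels: "
                f"{list(recording.channels)}"
            )
    for foot in feet:
        for site in ("heel", "ball"):
            if f"{foot}_{site}" not in recording.channels:
                raise SchemaError(f"recording lacks channel {foot}_{site}")

    filtered = _prefiltered(recording, params.filter)
    # streaming detectors run on pre-filtered samples; FilterConfig is
    # consumed above, so the per-foot machines take it as already applied
    labels: dict[str, np.ndarray] = {}
    traces: dict[str, dict[str, ChannelTrace]] = {}
    for foot in feet:
        det = FootDetector(params)
        heel_series = filtered[f"{foot}_heel"]
        ball_series = filtered[f"{foot}_ball"]
        foot_labels = np.empty(recording.n_samples, dtype=object)
        heel_trace, ball_trace = ChannelTrace(), ChannelTrace()
        for i in range(recording.n_samples):
            heel_area, heel_status = det.heel.step(float(heel_series[i]))
            ball_area, ball_status = det.ball.step(float(ball_series[i]))
            foot_labels[i] = classify_pattern(
                heel_area, heel_status, ball_area, ball_status, params.rule_mode
            )
            heel_trace.areas.append(heel_area)
            heel_trace.raw_areas.append(det.heel.raw_area)
            heel_trace.statuses.append(heel_status)
            ball_trace.areas.append(ball_area)
            ball_trace.raw_areas.append(det.ball.raw_area)
            ball_trace.statuses.append(ball_status)
        heel_trace.thresholds = det.heel.thresholds
        ball_trace.thresholds = det.ball.thresholds
        labels[foot] = foot_labels
        traces[foot] = {"heel": heel_trace, "ball": ball_trace}
    return GaitPatternSeries(labels=labels), traces
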