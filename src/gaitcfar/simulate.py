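"""Seeded synthetic gait generator with per-sample ground truth.

Emulates treadmill walking at 2–6 km/h as recorded by heel and ball
force sensors: per gait cycle the heel channel carries a smooth force
hump spanning early-to-mid stance and the ball a lagged hump spanning
mid-to-late stance, each peaking near 60 % of body mass; off-ground
samples carry i.i.d. noise whose magnitude is Rayleigh distributed —
the statistical structure the detector's threshold rule assumes.  The
right foot is the left shifted by half a cycle.

Cycle duration follows a simple cadence model, monotone decreasing in
speed:

    cycle_s = 1.4 / (0.35 + 0.15 * speed_kmh)

(≈2.15 s at 2 km/h down to ≈1.12 s at 6 km/h, in the range reported for
adult treadmill walking).  The force hump is ``peak * sin(pi * u)**0.25``
over the active fraction of the cycle: strictly monotone on either side
of a single maximum (so the window detector sees clean runs) with steep
shoulders (so ground-truth transition instants, defined at 1 %-of-body-
mass crossings, sit at the hump edges).  Ground-truth gait phases follow
the four-phase template from the per-channel on-ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .io import GCFRecording
from .patterns import PATTERN_FROM_STATUS_PAIR, GaitPatternSeries

__all__ = [
    "SyntheticGaitSpec",
    "LabeledRecording",
    "cycle_duration_s",
    "simulate_recording",
    "simulate_off_ground_noise",
]

#: hump shape exponent; < 1 gives steep shoulders and a broad single peak
_PULSE_SHARPNESS = 0.25
#: ground-truth contact threshold as a fraction of body mass
_TRUTH_FRACTION = 0.01
#: peak force as a fraction of body mass per sensor site
_PEAK_FRACTION = 0.6


@dataclass(frozen=True)
class SyntheticGaitSpec:
    """Conditions of one synthetic walking trial.

    ``tremble`` lists short swing-phase artefact bursts as
    ``(start_sample, length_samples, amplitude_kgf)`` tuples; bursts are
    added to off-ground samples only (a trembling foot in the air).
    """

    speed_kmh: float = 4.0
    duration_s: float = 30.0
    fs: float = 1000.0
    body_mass_kg: float = 68.2
    stance_fraction: float = 0.60
    heel_ball_lag_fraction: float = 0.15
    noise_sigma_kgf: float = 0.3
    tremble: Optional[Sequence[tuple[int, int, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if not 2.0 <= self.speed_kmh <= 6.0:
            raise ConfigError("speed_kmh must lie in [2, 6]")
        if not 0 < self.stance_fraction < 1:
            raise ConfigError("stance_fraction must lie in (0, 1)")
        if not 0 < self.heel_ball_lag_fraction < self.stance_fraction:
            raise ConfigError("heel_ball_lag_fraction must lie in (0, stance_fraction)")
        if self.noise_sigma_kgf < 0:
            raise ConfigError("noise_sigma_kgf must be non-negative")
        if self.body_mass_kg <= 0:
            raise ConfigError("body_mass_kg must be positive")
        for burst in self.tremble or ():
            start, length, amp = burst
            if start < 0 or length < 1 or amp < 0:
                raise ConfigError(f"invalid tremble burst {burst!r}")


@dataclass
class LabeledRecording:
    """A recording plus its generating ground truth.

    ``truth`` maps foot -> per-sample gait phases; ``truth_status`` maps
    channel -> per-sample boolean on-ground state.  The two are
    consistent under the (heel, ball) -> phase mapping by construction.
    """

    recording: GCFRecording
    truth: GaitPatternSeries
    truth_status: dict[str, np.ndarray] = field(default_factory=dict)


def cycle_duration_s(speed_kmh: float) -> float:
    """Gait-cycle duration (s) of the cadence model, decreasing in speed."""
    return 1.4 / (0.35 + 0.15 * speed_kmh)


def _hump(phase: np.ndarray, start: float, width: float, peak: float) -> np.ndarray:
    """Single-peaked force hump over the cycle-phase window [start, start+width)."""
    u = (phase - start) % 1.0
    y = np.zeros_like(phase)
    active = u < width
    y[active] = peak * np.sin(np.pi * u[active] / width) ** _PULSE_SHARPNESS
    return y


def simulate_off_ground_noise(n: int, sigma: float, seed: int = 0) -> np.ndarray:
    """n i.i.d. samples with Rayleigh(sigma)-distributed magnitude."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.zeros(n)
    return rng.rayleigh(scale=sigma, size=n)


def simulate_recording(spec: SyntheticGaitSpec) -> LabeledRecording:
    """Generate a labeled two-foot recording for *spec* (deterministic in seed)."""
    n = int(round(spec.duration_s * spec.fs))
    if n < 2:
        raise ConfigError("duration too short for the sampling rate")
    cycle = cycle_duration_s(spec.speed_kmh)
    t = np.arange(n) / spec.fs
    peak = _PEAK_FRACTION * spec.body_mass_kg
    truth_level = _TRUTH_FRACTION * spec.body_mass_kg
    heel_width = spec.stance_fraction - spec.heel_ball_lag_fraction
    rng = np.random.default_rng(spec.seed)

    channels: dict[str, np.ndarray] = {}
    truth_status: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}
    for foot, phase_offset in (("left", 0.0), ("right", 0.5)):
        phase = (t / cycle + phase_offset) % 1.0
        clean = {
            "heel": _hump(phase, 0.0, heel_width, peak),
            "ball": _hump(
                phase, spec.heel_ball_lag_fraction, heel_width, peak
            ),
        }
        on = {site: clean[site] >= truth_level for site in clean}
        for site in ("heel", "ball"):
            noise = (
                rng.rayleigh(scale=spec.noise_sigma_kgf, size=n)
                if spec.noise_sigma_kgf > 0
                else np.zeros(n)
            )
            signal = np.where(on[site], clean[site], noise)
            for start, length, amp in spec.tremble or ():
                stop = min(start + length, n)
                if start >= n:
                    continue
                burst = amp * np.sin(
                    np.pi * np.arange(stop - start) / length
                ) ** 2
                seg = slice(start, stop)
                off = ~on[site][seg]
                signal[seg] = np.where(off, signal[seg] + burst, signal[seg])
            channels[f"{foot}_{site}"] = signal
            truth_status[f"{foot}_{site}"] = on[site]
        truth[foot] = np.asarray(
            [
                PATTERN_FROM_STATUS_PAIR[(int(h), int(b))]
                for h, b in zip(on["heel"], on["ball"])
            ],
            dtype=object,
        )

    recording = GCFRecording(
        fs=spec.fs,
        channels=channels,
        subject_meta={
            "body_mass_kg": spec.body_mass_kg,
            "speed_kmh": spec.speed_kmh,
        },
    )
    return LabeledRecording(
        recording=recording,
        truth=GaitPatternSeries(labels=truth),
        truth_status=truth_status,
    )
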