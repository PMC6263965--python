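"""Gait-pattern vocabulary and per-foot label series."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["GaitPattern", "GaitPatternSeries", "PATTERN_FROM_STATUS_PAIR", "eq_label"]


class GaitPattern(str, Enum):
    """Per-sample gait phase of one foot.

    The four phases follow from which of the two sensor sites carries
    load: heel only marks the swing-to-stance transition (Heel-Strike),
    ball only marks the stance-to-swing transition (Heel-Off), both mark
    Full-Stance and neither marks Swing.  UNDEFINED appears only during
    detector warm-up, before a channel has its first adaptive threshold.
    """

    HEEL_STRIKE = "HEEL_STRIKE"
    FULL_STANCE = "FULL_STANCE"
    HEEL_OFF = "HEEL_OFF"
    SWING = "SWING"
    UNDEFINED = "UNDEFINED"


def eq_label(arr: np.ndarray, label: "GaitPattern") -> np.ndarray:
    """Elementwise ``arr == label`` for object arrays of labels.

    numpy treats a bare str-mixin enum scalar as a character sequence
    before broadcasting; assigning it into a 0-d object array compares
    the enum itself.
    """
    scalar = np.empty((), dtype=object)
    scalar[()] = label
    return np.asarray(arr, dtype=object) == scalar


#: (heel_on, ball_on) -> phase
PATTERN_FROM_STATUS_PAIR = {
    (1, 1): GaitPattern.FULL_STANCE,
    (1, 0): GaitPattern.HEEL_STRIKE,
    (0, 1): GaitPattern.HEEL_OFF,
    (0, 0): GaitPattern.SWING,
}


@dataclass
class GaitPatternSeries:
    """Per-sample gait-phase labels for one or both feet.

    ``labels`` maps foot name ("left"/"right") to an object array of
    :class:`GaitPattern`, all of equal length.
    """

    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        lengths = set()
        for foot, arr in self.labels.items():
            a = np.asarray(
                [GaitPattern(x) for x in arr], dtype=object
            )
            clean[foot] = a
            lengths.add(a.size)
        if len(lengths) > 1:
            raise ValueError(f"feet have unequal label lengths: {sorted(lengths)}")
        self.labels = clean

    @property
    def n_samples(self) -> int:
        for arr in self.labels.values():
            return int(arr.size)
        return 0

    @property
    def feet(self) -> list[str]:
        return list(self.labels)

    def __getitem__(self, foot: str) -> np.ndarray:
        return self.labels[foot]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GaitPatternSeries):
            return NotImplemented
        if self.feet != other.feet:
            return False
        return all(
            np.array_equal(self.labels[f], other.labels[f]) for f in self.feet
        )
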