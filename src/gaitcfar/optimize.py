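"""Exhaustive (traversing) search for detector parameters.

Window sizes/limits are selected against known off-ground force data by
the *testing probability*: the fraction of off-ground samples the window
detector misclassifies into a continuous area.  Among all parameter
combinations whose testing probability is zero, the smallest is chosen
(larger windows only add detection lag).  The false-alarm parameter is
selected by maximising mean label agreement against reference-labelled
training recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cfar import PfMode
from .detector import DetectorParams, run_offline
from .errors import ConfigError
from .evaluation import series_agreement
from .io import GCFRecording
from .patterns import GaitPatternSeries
from .windows import CODE_UNSTABLE, WindowParams, area_label_codes

__all__ = [
    "testing_probability",
    "WindowGridResult",
    "grid_search_windows",
    "grid_search_pf",
]

log = logging.getLogger(__name__)


def testing_probability(off_ground, params: WindowParams) -> float:
    """Fraction of off-ground samples labelled into a continuous area.

    The first sample (no difference yet) is excluded.  Zero is the
    selection criterion: the windows should never see a long monotone run
    in pure noise.
    """
    x = np.asarray(off_ground, dtype=float)
    if x.size <= max(params.asc_size, params.desc_size):
        raise ValueError(
            f"series of {x.size} samples is shorter than the largest window"
        )
    codes = area_label_codes(x, params)
    return float(np.mean(codes[1:] != CODE_UNSTABLE))


@dataclass
class WindowGridResult:
    """Outcome of the window-parameter traversing search."""

    grid: pd.DataFrame  # columns: asc_limit, asc_size, desc_limit, desc_size, testing_probability
    zero_set: pd.DataFrame
    selected: Optional[WindowParams]


def _side_masks(
    diff_positive_cumsum: np.ndarray,
    sizes: Sequence[int],
    limits: Sequence[int],
    n: int,
) -> dict[tuple[int, int], np.ndarray]:
    """Boolean exceed-mask per (limit, size) combo for one window side."""
    idx = np.arange(1, n)
    masks = {}
    counts_by_size = {}
    for size in sorted(set(sizes)):
        counts_by_size[size] = (
            diff_positive_cumsum[idx]
            - diff_positive_cumsum[np.maximum(idx - size, 0)]
        )
    for limit in sorted(set(limits)):
        for size in sorted(set(sizes)):
            if 0 < limit < size:
                masks[(limit, size)] = counts_by_size[size] > limit
    return masks


def grid_search_windows(
    off_ground,
    asc_limits: Sequence[int],
    asc_sizes: Sequence[int],
    desc_limits: Sequence[int],
    desc_sizes: Sequence[int],
) -> WindowGridResult:
    """Traverse every admissible window-parameter combination.

    Admissible combos satisfy limit < size on both sides and the
    no-overlap condition of :class:`WindowParams`.  The selected combo is
    the zero-testing-probability one minimising total window size
    (asc_size + desc_size), ties broken by smaller total limit, then
    lexicographically — "smallest" because bigger windows lag more.
    """
    for name, rng_ in (
        ("asc_limits", asc_limits),
        ("asc_sizes", asc_sizes),
        ("desc_limits", desc_limits),
        ("desc_sizes", desc_sizes),
    ):
        if len(list(rng_)) == 0:
            raise ConfigError(f"empty range for {name}")
    x = np.asarray(off_ground, dtype=float)
    n = x.size
    if n <= max(list(asc_sizes) + list(desc_sizes)):
        raise ValueError("off-ground series shorter than the largest window")
    d = np.diff(x)
    pos_cs = np.concatenate(([0], np.cumsum(d > 0)))
    neg_cs = np.concatenate(([0], np.cumsum(d < 0)))
    asc_masks = _side_masks(pos_cs, asc_sizes, asc_limits, n)
    desc_masks = _side_masks(neg_cs, desc_sizes, desc_limits, n)

    rows = []
    for (la, na), ma in sorted(asc_masks.items()):
        for (ld, nd), md in sorted(desc_masks.items()):
            if la + ld + 2 <= max(na, nd):  # overlap-admitting combo
                continue
            prob = float(np.mean(ma | md))
            rows.append((la, na, ld, nd, prob))
    grid = pd.DataFrame(
        rows,
        columns=["asc_limit", "asc_size", "desc_limit", "desc_size", "testing_probability"],
    )
    zero_set = grid[grid.testing_probability == 0.0].reset_index(drop=True)
    if zero_set.empty:
        log.warning("no parameter combination achieves zero testing probability")
        selected = None
    else:
        best = zero_set.assign(
            total_size=zero_set.asc_size + zero_set.desc_size,
            total_limit=zero_set.asc_limit + zero_set.desc_limit,
        ).sort_values(
            ["total_size", "total_limit", "asc_limit", "asc_size", "desc_limit", "desc_size"]
        ).iloc[0]
        selected = WindowParams(
            asc_size=int(best.asc_size),
            asc_limit=int(best.asc_limit),
            desc_size=int(best.desc_size),
            desc_limit=int(best.desc_limit),
        )
    return WindowGridResult(grid=grid, zero_set=zero_set, selected=selected)


def grid_search_pf(
    training: Sequence[tuple[GCFRecording, GaitPatternSeries]],
    pf_grid: Sequence[float],
    pf_mode: PfMode | str = PfMode.INVERSE_GAIN,
    base_params: Optional[DetectorParams] = None,
) -> tuple[float, pd.DataFrame]:
    """Pick the false-alarm value maximising mean agreement on training data.

    *training* pairs recordings with their reference label series.
    Returns the best value and the full score table (one row per grid
    value) for plotting.
    """
    pf_grid = list(pf_grid)
    if not pf_grid:
        raise ConfigError("empty false-alarm grid")
    if not training:
        raise ConfigError("need at least one training recording")
    base = base_params or DetectorParams()
    rows = []
    for pf in pf_grid:
        params = replace(base, cfar=replace(base.cfar, pf_value=pf, pf_mode=pf_mode))
        scores = []
        for recording, reference in training:
            detected, _ = run_offline(recording, params)
            scores.append(series_agreement(detected, reference))
        rows.append((pf, float(np.mean(scores))))
    table = pd.DataFrame(rows, columns=["pf_value", "mean_agreement_pct"])
    best = table.loc[table.mean_agreement_pct.idxmax(), "pf_value"]
    return float(best), table
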