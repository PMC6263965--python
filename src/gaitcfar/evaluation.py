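"""Agreement between label series and one-way intraclass correlation.

Reliability between two detectors is the percentage of samples on which
their per-sample gait-phase labels agree, with warm-up (UNDEFINED)
samples excluded pairwise.  Test–retest consistency of a subjects x
measurements reliability table is summarised by the one-way
random-effects, single-measurement intraclass correlation

    ICC(1,1) = (BMS - WMS) / (BMS + (k - 1) WMS)

with BMS/WMS the between-/within-subject mean squares of a one-way ANOVA
and k the number of measurements per subject; the estimate may be
negative.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .patterns import GaitPattern, GaitPatternSeries, eq_label

__all__ = [
    "agreement",
    "series_agreement",
    "icc_oneway",
    "load_reliability_table",
    "collapse_runs",
]


def _as_label_array(seq) -> np.ndarray:
    if isinstance(seq, GaitPatternSeries):
        raise TypeError("pass one foot's labels or use series_agreement()")
    return np.asarray([GaitPattern(x) for x in seq], dtype=object)


def agreement(a: Sequence, b: Sequence) -> float:
    """Percentage of samples with equal labels, UNDEFINED excluded pairwise.

    Raises if the lengths differ or no comparable sample remains.
    """
    a_arr, b_arr = _as_label_array(a), _as_label_array(b)
    if a_arr.size != b_arr.size:
        raise ValueError(f"length mismatch: {a_arr.size} vs {b_arr.size}")
    comparable = ~eq_label(a_arr, GaitPattern.UNDEFINED) & ~eq_label(
        b_arr, GaitPattern.UNDEFINED
    )
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable samples (all UNDEFINED)")
    matches = int((a_arr[comparable] == b_arr[comparable]).sum())
    return 100.0 * matches / n


def series_agreement(a: GaitPatternSeries, b: GaitPatternSeries) -> float:
    """Agreement pooled over the feet both series share."""
    feet = [f for f in a.feet if f in b.feet]
    if not feet:
        raise ValueError("series share no feet")
    a_all = np.concatenate([a[f] for f in feet])
    b_all = np.concatenate([b[f] for f in feet])
    return agreement(a_all, b_all)


def icc_oneway(table) -> float:
    """One-way random-effects, single-measurement ICC of a rectangular table.

    Rows are subjects, columns repeated measurements; needs at least a
    2 x 2 complete table with non-zero total variance.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError(f"need a table of at least 2x2, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("table contains missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("table has zero total variance; ICC undefined")
    row_means = x.mean(axis=1)
    bms = k * np.sum((row_means - grand) ** 2) / (n - 1)
    wms = np.sum((x - row_means[:, None]) ** 2) / (n * (k - 1))
    return float((bms - wms) / (bms + (k - 1) * wms))


def load_reliability_table() -> pd.DataFrame:
    """Bundled example reliability table (22 subjects x 5 reference methods).

    Per-subject agreement percentages of an adaptive gait-phase detector
    against five fixed-threshold reference detectors, indexed by subject
    with a ``gender`` column; the five method columns are the
    measurements for ICC demonstrations.
    """
    with resources.files("gaitcfar.data").joinpath("reliability_table.csv").open() as f:
        df = pd.read_csv(f, index_col="subject")
    return df


def collapse_runs(labels, drop_undefined: bool = True) -> list[GaitPattern]:
    """Collapse consecutive equal labels into a run sequence.

    Useful for checking the cyclic phase order Heel-Strike -> Full-Stance
    -> Heel-Off -> Swing of an emitted series.
    """
    arr = _as_label_array(labels)
    if drop_undefined:
        arr = arr[~eq_label(arr, GaitPattern.UNDEFINED)]
    runs: list[GaitPattern] = []
    for lab in arr:
        if not runs or runs[-1] is not lab:
            runs.append(lab)
    return runs
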