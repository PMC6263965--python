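"""Sliding-window segmentation: updates, counts, labels, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitcfar.errors import ConfigError
from gaitcfar.windows import (
    AreaLabel,
    CODE_TO_LABEL,
    WindowParams,
    area_label_codes,
    classify,
    init_state,
    label_series,
    update,
)


def brute_counts(series, asc_size, desc_size, i):
    """Independent recount: sign tallies over the last diffs up to sample i."""
    d = np.sign(np.diff(np.asarray(series[: i + 1], dtype=float)))
    return int(np.sum(d[-asc_size:] > 0)), int(np.sum(d[-desc_size:] < 0))


class TestParams:
    def test_defaults_are_optimised_values(self):
        p = WindowParams()
        assert (p.asc_limit, p.asc_size, p.desc_limit, p.desc_size) == (35, 38, 36, 40)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(asc_limit=38, asc_size=38),  # limit not < size
            dict(asc_limit=0),
            dict(desc_limit=45, desc_size=40),
            dict(asc_size=38.0),  # non-integer
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            WindowParams(**{**dict(), **kwargs})

    def test_overlap_admitting_params_rejected(self):
        # 1 + 1 + 2 <= 10: a stream can satisfy both count conditions at once
        with pytest.raises(ConfigError, match="simultaneous"):
            WindowParams(asc_size=10, asc_limit=1, desc_size=10, desc_limit=1)


class TestUpdate:
    def test_init_all_zero(self, default_windows):
        s = init_state(default_windows)
        assert len(s.asc_bits) == 38 and len(s.desc_bits) == 40
        assert s.asc_count == 0 and s.desc_count == 0 and s.prev_force is None

    def test_monotone_rise_fills_ascending_window(self):
        p = WindowParams(asc_size=3, asc_limit=2, desc_size=3, desc_limit=2)
        s = init_state(p)
        for f in (1, 2, 3, 4):
            update(s, f)
        assert list(s.asc_bits) == [1, 1, 1] and s.asc_count == 3
        assert list(s.desc_bits) == [0, 0, 0] and s.desc_count == 0

    def test_alternating_rise_fall(self):
        p = WindowParams(asc_size=3, asc_limit=2, desc_size=3, desc_limit=2)
        s = init_state(p)
        for f in (1, 2, 1, 2):
            update(s, f)
        assert s.asc_count == 2 and s.desc_count == 1

    def test_zero_diff_supports_neither_window(self, default_windows):
        s = init_state(default_windows)
        for f in (5.0, 5.0, 5.0):
            update(s, f)
        assert s.asc_count == 0 and s.desc_count == 0

    def test_non_finite_force_rejected(self, default_windows):
        s = init_state(default_windows)
        with pytest.raises(ValueError):
            update(s, float("nan"))


class TestClassify:
    def test_count_above_limit_is_ascending(self, default_windows):
        s = init_state(default_windows)
        for f in range(38):  # 37 rising diffs
            update(s, float(f))
        assert s.asc_count == 37
        assert classify(s, default_windows) is AreaLabel.CONTINUOUS_ASCENDING

    def test_boundary_count_is_strict(self, default_windows):
        s = init_state(default_windows)
        for f in range(36):  # exactly 35 rising diffs
            update(s, float(f))
        assert s.asc_count == 35
        assert classify(s, default_windows) is AreaLabel.UNSTABLE
        update(s, 100.0)  # the 36th makes it continuous
        assert classify(s, default_windows) is AreaLabel.CONTINUOUS_ASCENDING

    def test_fresh_state_unstable(self, default_windows):
        assert classify(init_state(default_windows), default_windows) is AreaLabel.UNSTABLE


class TestLabelSeries:
    def test_ramp_turns_ascending_and_stays(self, default_windows):
        labels, events = label_series(np.arange(100.0), default_windows)
        assert labels[0] is AreaLabel.UNSTABLE
        first_asc = next(i for i, l in enumerate(labels) if l is AreaLabel.CONTINUOUS_ASCENDING)
        assert first_asc == 36  # 36 positive diffs strictly exceed the limit of 35
        assert all(l is AreaLabel.CONTINUOUS_ASCENDING for l in labels[36:])
        assert events == [(36, AreaLabel.CONTINUOUS_ASCENDING)]

    def test_alternating_signs_stay_unstable(self, default_windows):
        series = np.tile([0.0, 1.0], 200)
        labels, events = label_series(series, default_windows)
        assert set(labels) == {AreaLabel.UNSTABLE} and events == []

    def test_too_short_series_rejected(self, default_windows):
        with pytest.raises(ValueError):
            label_series([1.0], default_windows)

    def test_shift_invariance(self, default_windows, rng):
        from conftest import random_force_stream

        x = random_force_stream(rng, 300)
        labels, _ = label_series(x, default_windows)
        shifted, _ = label_series(x + 123.4, default_windows)
        assert labels == shifted


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(st.integers(min_value=-3, max_value=3), min_size=2, max_size=120),
    asc_size=st.integers(3, 9),
    desc_size=st.integers(3, 9),
    asc_frac=st.floats(0.2, 0.99),
    desc_frac=st.floats(0.2, 0.99),
)
def test_incremental_counts_match_brute_recount(data, asc_size, desc_size, asc_frac, desc_frac):
    """After every update the window counts equal a full recount of the stream."""
    asc_limit = max(1, int(asc_frac * (asc_size - 1)))
    desc_limit = max(1, int(desc_frac * (desc_size - 1)))
    if asc_limit + desc_limit + 2 <= max(asc_size, desc_size):
        return  # overlap-admitting combination: rejected by the validator
    params = WindowParams(
        asc_size=asc_size, asc_limit=asc_limit, desc_size=desc_size, desc_limit=desc_limit
    )
    series = np.cumsum(data).astype(float)
    state = init_state(params)
    for i, f in enumerate(series):
        update(state, f)
        ca, cd = brute_counts(series, asc_size, desc_size, i)
        assert (state.asc_count, state.desc_count) == (ca, cd)


def test_vectorised_labels_match_streaming(default_windows, rng):
    from conftest import random_force_stream

    for _ in range(20):
        x = random_force_stream(rng, 400)
        streamed, _ = label_series(x, default_windows)
        codes = area_label_codes(x, default_windows)
        assert [CODE_TO_LABEL[int(c)] for c in codes] == streamed
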