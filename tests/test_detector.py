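"""Gait-phase state machine: rule table, streaming contract, end-to-end."""

import time

import numpy as np
import pytest

from gaitcfar.cfar import ContactStatus
from gaitcfar.detector import (
    DetectorParams,
    FootDetector,
    RuleMode,
    classify_pattern,
    run_offline,
)
from gaitcfar.errors import SchemaError
from gaitcfar.evaluation import agreement, collapse_runs
from gaitcfar.filters import FilterConfig, FilterMode, StreamingLowpass
from gaitcfar.io import GCFRecording
from gaitcfar.patterns import GaitPattern, eq_label
from gaitcfar.simulate import SyntheticGaitSpec, simulate_recording
from gaitcfar.windows import AreaLabel

PHASE_CYCLE = [
    GaitPattern.HEEL_STRIKE,
    GaitPattern.FULL_STANCE,
    GaitPattern.HEEL_OFF,
    GaitPattern.SWING,
]


def assert_cyclic_order(labels):
    """Collapsed run sequence must walk the 4-phase cycle without skips."""
    runs = collapse_runs(labels)
    assert len(runs) >= 8, "too few phase runs to assess ordering"
    start = PHASE_CYCLE.index(runs[1])
    for offset, run in enumerate(runs[1:]):
        assert run is PHASE_CYCLE[(start + offset) % 4], f"order break at run {offset}: {runs[:offset+3]}"


class TestClassifyPattern:
    @staticmethod
    def expected(heel_area, heel_status, ball_area, ball_status, mode):
        """Independent statement of the rule table."""
        if (
            mode is RuleMode.TABLE1_LITERAL
            and heel_area is AreaLabel.UNSTABLE
            and ball_area is AreaLabel.UNSTABLE
        ):
            return GaitPattern.FULL_STANCE
        eff = {}
        for name, area, status in (
            ("heel", heel_area, heel_status),
            ("ball", ball_area, ball_status),
        ):
            if area is AreaLabel.UNSTABLE:
                eff[name] = 0
            elif status is ContactStatus.UNDEFINED:
                eff[name] = None
            else:
                eff[name] = int(status is ContactStatus.ON_GROUND)
        if eff["heel"] is None or eff["ball"] is None:
            return GaitPattern.UNDEFINED
        return {
            (1, 1): GaitPattern.FULL_STANCE,
            (1, 0): GaitPattern.HEEL_STRIKE,
            (0, 1): GaitPattern.HEEL_OFF,
            (0, 0): GaitPattern.SWING,
        }[(eff["heel"], eff["ball"])]

    @pytest.mark.parametrize("mode", list(RuleMode))
    def test_exhaustive_truth_table(self, mode):
        for ha in AreaLabel:
            for hs in ContactStatus:
                for ba in AreaLabel:
                    for bs in ContactStatus:
                        assert classify_pattern(ha, hs, ba, bs, mode) is self.expected(
                            ha, hs, ba, bs, mode
                        )

    def test_printed_rule_rows(self):
        """The five distinct rows of the published detection rule."""
        asc, uns = AreaLabel.CONTINUOUS_ASCENDING, AreaLabel.UNSTABLE
        on, off = ContactStatus.ON_GROUND, ContactStatus.OFF_GROUND
        lit = RuleMode.TABLE1_LITERAL
        # heel continuous+on, ball unstable -> Heel-Strike
        assert classify_pattern(asc, on, uns, off, lit) is GaitPattern.HEEL_STRIKE
        # heel continuous+off, ball unstable -> Swing
        assert classify_pattern(asc, off, uns, off, lit) is GaitPattern.SWING
        # heel unstable, ball continuous+on -> Heel-Off
        assert classify_pattern(uns, off, asc, on, lit) is GaitPattern.HEEL_OFF
        # both continuous: (on, on) -> Full-Stance, (off, off) -> Swing
        assert classify_pattern(asc, on, asc, on, lit) is GaitPattern.FULL_STANCE
        assert classify_pattern(asc, off, asc, off, lit) is GaitPattern.SWING
        # both unstable: literal row says Full-Stance, default says Swing
        assert classify_pattern(uns, off, uns, off, lit) is GaitPattern.FULL_STANCE
        assert classify_pattern(uns, off, uns, off) is GaitPattern.SWING


class TestStepContract:
    def test_flat_input_is_swing_throughout(self):
        det = FootDetector()
        patterns = [det.step(3.0, 3.0) for _ in range(200)]
        assert all(p is GaitPattern.SWING for p in patterns)

    def test_warmup_ascent_without_threshold_is_undefined(self):
        det = FootDetector()
        out = []
        for i in range(120):  # heel ramps up; too few unstable samples to seed a threshold
            out.append(det.step(float(i), 0.0))
        assert out[0] is GaitPattern.SWING
        assert out[50] is GaitPattern.UNDEFINED
        assert det.heel.record is None

    def test_threshold_records_strictly_ordered(self, short_walk):
        _, traces = run_offline(short_walk.recording)
        for foot in traces:
            for site in ("heel", "ball"):
                at = [r.computed_at for r in traces[foot][site].thresholds]
                assert at == sorted(at) and len(set(at)) == len(at)
                assert len(at) >= 3

    def test_constant_work_per_sample(self, rng):
        """Per-sample cost on a 10x longer stream stays within 2x (no rescans)."""

        def rate(n):
            heel = rng.rayleigh(0.3, n)
            ball = rng.rayleigh(0.3, n)
            best = np.inf
            for _ in range(3):
                det = FootDetector(DetectorParams(filter=FilterConfig(mode="off")))
                t0 = time.perf_counter()
                for h, b in zip(heel, ball):
                    det.step(h, b)
                best = min(best, (time.perf_counter() - t0) / n)
            return best

        assert rate(30000) < 2.0 * rate(3000)


class TestRunOffline:
    def test_missing_channel_is_schema_error(self):
        rec = GCFRecording(fs=500.0, channels={"left_heel": np.zeros(100) + 1})
        with pytest.raises(SchemaError):
            run_offline(rec)
        with pytest.raises(SchemaError):
            run_offline(rec, feet=["left"])

    def test_batch_equals_streaming(self, rng):
        params = DetectorParams(filter=FilterConfig(mode=FilterMode.OFF))
        for _ in range(10):
            n = 400
            rec = GCFRecording(
                fs=500.0,
                channels={
                    "left_heel": np.abs(np.cumsum(rng.normal(0, 1, n))),
                    "left_ball": rng.rayleigh(0.5, n),
                },
            )
            batch, _ = run_offline(rec, params)
            det = FootDetector(params)
            streamed = [
                det.step(h, b)
                for h, b in zip(rec.channels["left_heel"], rec.channels["left_ball"])
            ]
            assert list(batch["left"]) == streamed

    def test_batch_equals_streaming_with_causal_filter(self, short_walk):
        params = DetectorParams()
        assert params.filter.mode is FilterMode.CAUSAL
        rec = short_walk.recording
        batch, _ = run_offline(rec, params, feet=["left"])
        det = FootDetector(params)
        heel_f = StreamingLowpass(rec.fs, params.filter)
        ball_f = StreamingLowpass(rec.fs, params.filter)
        streamed = [
            det.step(heel_f.process_sample(h), ball_f.process_sample(b))
            for h, b in zip(rec.channels["left_heel"], rec.channels["left_ball"])
        ]
        assert list(batch["left"]) == streamed


class TestEndToEnd:
    @pytest.mark.parametrize("speed", [2.0, 6.0])
    def test_phase_order_and_agreement(self, speed):
        lab = simulate_recording(
            SyntheticGaitSpec(speed_kmh=speed, duration_s=8.0, fs=500.0, seed=21)
        )
        series, _ = run_offline(lab.recording)
        for foot in ("left", "right"):
            assert_cyclic_order(series[foot])
            truth = lab.truth[foot]
            # the window detector reports transitions with a fixed ~38-sample
            # lag; outside those bands the labels must agree
            transitions = np.flatnonzero(truth[1:] != truth[:-1]) + 1
            idx = np.arange(truth.size)
            dist = np.min(np.abs(idx[:, None] - transitions[None, :]), axis=1)
            outside = dist > 38
            assert agreement(series[foot][outside], truth[outside]) > 95.0

    def test_tremble_never_full_stance_in_default_mode(self):
        bursts = [(2200, 30, 10.0), (2300, 34, 25.0), (3600, 20, 6.0)]
        lab = simulate_recording(
            SyntheticGaitSpec(
                speed_kmh=4.0, duration_s=8.0, fs=500.0, seed=5, tremble=bursts
            )
        )
        series, _ = run_offline(lab.recording)
        for foot in ("left", "right"):
            swing_truth = eq_label(lab.truth[foot], GaitPattern.SWING)
            detected_fs = eq_label(series[foot], GaitPattern.FULL_STANCE)
            assert not np.any(swing_truth & detected_fs)
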