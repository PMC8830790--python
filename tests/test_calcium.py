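"""ΔF/F conversion, ON/OFF responses, OFF latency, group summaries."""

import statistics

import numpy as np
import pytest

from odorint.calcium import (
    DffTrace,
    FluorescenceTrace,
    InsufficientBaselineError,
    ResponseWindows,
    baseline,
    default_windows,
    dff,
    off_latency,
    off_response,
    on_response,
    quantify,
    summarize_group,
)

DT = 0.2


def make_trace(F, t_onset=10.0, t_removal=40.0, neuron="AWB", tid="t1"):
    F = np.asarray(F, dtype=float)
    t = np.arange(len(F)) * DT
    return FluorescenceTrace(tid, neuron, "wild_type", "nonanone", t, F, t_onset, t_removal)


def step_trace(base=100.0, during=150.0, after=100.0, t_onset=10.0, t_removal=40.0,
               total=90.0, **kw):
    t = np.arange(int(round(total / DT))) * DT
    F = np.full_like(t, base)
    F[(t >= t_onset) & (t < t_removal)] = during
    F[t >= t_removal] = after
    return make_trace(F, t_onset, t_removal, **kw)


class TestBaselineAndDff:
    def test_constant_baseline(self):
        assert baseline(step_trace(during=100.0)) == pytest.approx(100.0)

    def test_alternating_baseline_mean(self):
        F = np.full(450, 100.0)
        F[:50:2], F[1:50:2] = 90.0, 110.0
        assert baseline(make_trace(F)) == pytest.approx(100.0)

    def test_ramp_baseline_equals_sample_sum(self):
        # ramp 100 -> 110 over the 10-s window; oracle: plain sum of frames
        t = np.arange(450) * DT
        F = np.full(450, 110.0)
        ramp = (t < 10.0)
        F[ramp] = 100.0 + t[ramp]
        expected = sum(F[:50]) / 50
        assert baseline(make_trace(F)) == pytest.approx(expected)

    def test_insufficient_baseline_rejected(self):
        with pytest.raises(InsufficientBaselineError):
            baseline(step_trace(t_onset=5.0))

    @pytest.mark.parametrize("during,expected", [(150.0, 50.0), (80.0, -20.0)])
    def test_dff_step_values(self, during, expected):
        d = dff(step_trace(during=during))
        stim = (d.time >= 10.0) & (d.time < 40.0)
        assert d.dff_pct[stim] == pytest.approx(expected)
        pre = d.time < 10.0
        assert d.dff_pct[pre].mean() == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="non-physical"):
            dff(step_trace(base=-1.0))

    def test_nonuniform_sampling_rejected(self):
        t = np.arange(450) * DT
        t[100] += 0.05
        with pytest.raises(ValueError, match="uniform"):
            FluorescenceTrace("t", "AWB", "wt", "iaa", t, np.ones(450), 10.0, 40.0)


class TestResponses:
    def test_zero_trace_zero_responses(self):
        d = dff(step_trace(during=100.0))
        for w in (default_windows("AWB"), default_windows("AVA"),
                  default_windows("AVA", "ava_late")):
            assert on_response(d, w) == 0.0
            assert off_response(d, w) == 0.0

    def test_step_on_response_any_window(self):
        d = dff(step_trace(during=150.0))
        assert on_response(d, default_windows("AWB")) == pytest.approx(50.0)
        assert on_response(d, default_windows("AVA", "ava_late")) == pytest.approx(50.0)

    def test_off_response_ash_sign_change(self):
        # dff -20% during the stimulus, +30% after removal: OFF = 30-(-20)
        d = dff(step_trace(during=80.0, after=130.0))
        assert off_response(d, default_windows("ASH")) == pytest.approx(50.0)

    def test_off_response_decay_to_baseline(self):
        d = dff(step_trace(during=150.0, after=100.0))
        assert off_response(d, default_windows("AWB")) == pytest.approx(-50.0)

    def test_window_past_trace_end_rejected(self):
        d = dff(step_trace(total=45.0))
        with pytest.raises(ValueError, match="window"):
            off_response(d, default_windows("AWB"))

    def test_multiplicative_scaling_invariance(self):
        tr = step_trace(during=150.0, after=130.0)
        scaled = make_trace(3.7 * tr.F)
        w = default_windows("AWB")
        assert on_response(dff(scaled), w) == pytest.approx(on_response(dff(tr), w))
        assert off_response(dff(scaled), w) == pytest.approx(off_response(dff(tr), w))
        assert dff(scaled).f_base == pytest.approx(3.7 * dff(tr).f_base)


def scan_oracle(time, values, t_removal, k_sd, cap):
    """Frame-by-frame latency scan with statistics-library moments."""
    pre = [v for t, v in zip(time, values) if t_removal - 10.0 <= t < t_removal]
    threshold = statistics.fmean(pre) + k_sd * statistics.stdev(pre)
    for t, v in zip(time, values):
        if t >= t_removal and v >= threshold:
            return t - t_removal, True
    return cap, False


class TestOffLatency:
    def test_never_crossing_returns_cap(self):
        rng = np.random.default_rng(0)
        F = np.full(450, 100.0)
        F[:200] += rng.normal(0, 1.0, 200)  # noisy pre/stim epochs, SD > 0
        tr = make_trace(F)
        lat, crossed = off_latency(dff(tr))
        assert (lat, crossed) == (40.0, False)

    def test_immediate_crossing(self):
        d = dff(step_trace(during=150.0, after=200.0))
        # jitter pre-removal window so SD > 0 but threshold << post level
        lat, crossed = off_latency(d)
        assert crossed and lat == 0.0

    def test_ramp_crossing_time(self):
        # pre-removal dff ~ N(0-mean jitter); post-removal ramp hits the
        # threshold first at a known frame
        t = np.arange(450) * DT
        F = np.full(450, 100.0)
        F[148:200:2] += 0.5
        F[149:200:2] -= 0.5
        after = t >= 40.0
        F[after] = 100.0 + 2.0 * (t[after] - 40.0)  # +2%/s ramp
        tr = make_trace(F)
        d = dff(tr)
        lat, crossed = off_latency(d)
        oracle = scan_oracle(d.time, d.dff_pct, 40.0, 3.0, 40.0)
        assert crossed
        assert (lat, crossed) == pytest.approx(oracle)

    def test_matches_frame_scan_oracle_on_random_traces(self, rng):
        for i in range(500):
            n = int(rng.integers(300, 451))
            F = 100.0 + rng.normal(0, 2.0, n).cumsum() * 0.1 + rng.normal(0, 1.0, n)
            t_rem = float(rng.choice([30.0, 40.0, 50.0]))
            tr = make_trace(np.maximum(F, 5.0), t_onset=10.0, t_removal=t_rem,
                            tid=f"r{i}")
            d = dff(tr)
            got = off_latency(d)
            want = scan_oracle(d.time, d.dff_pct, t_rem, 3.0, 40.0)
            assert got == pytest.approx(want)

    def test_latency_nondecreasing_in_k_sd(self):
        t = np.arange(450) * DT
        F = np.full(450, 100.0)
        F[148:200:2] += 1.0
        after = t >= 40.0
        F[after] = 100.0 + 1.0 * (t[after] - 40.0)
        d = dff(make_trace(F))
        lats = [off_latency(d, k_sd=k)[0] for k in (1.0, 2.0, 3.0, 5.0)]
        assert all(a <= b for a, b in zip(lats, lats[1:]))

    def test_insufficient_pre_removal_rejected(self):
        # recording cropped to start just one frame before removal
        t = 39.8 + np.arange(100) * DT
        d = DffTrace("crop", "AWB", t, np.zeros(100), 100.0, 10.0, 40.0)
        with pytest.raises(ValueError, match="pre-removal"):
            off_latency(d)


class TestGroupSummary:
    def test_single_trace_mean_is_trace(self):
        d = dff(step_trace(during=150.0))
        s = summarize_group([d])
        assert s.mean == pytest.approx(d.dff_pct)
        assert s.sem == pytest.approx(np.zeros_like(d.dff_pct))

    def test_two_constant_traces(self):
        d0 = dff(step_trace(during=100.0, after=100.0, tid="a"))
        F = np.full(450, 100.0)
        F[50:] = 110.0
        d10 = dff(make_trace(F, tid="b"))
        s = summarize_group([d0, d10])
        post = s.time >= 0.0
        assert s.mean[post] == pytest.approx(5.0)
        assert s.sem[post] == pytest.approx(5.0)  # SD 7.071 / sqrt(2)

    def test_identical_traces_zero_sem(self):
        traces = [dff(step_trace(during=140.0, tid=f"t{i}")) for i in range(4)]
        s = summarize_group(traces)
        assert s.sem == pytest.approx(np.zeros_like(s.sem))
        assert s.n == 4

    def test_mismatched_grids_rejected(self):
        a = dff(step_trace(tid="a"))
        b = dff(step_trace(total=80.0, tid="b"))
        with pytest.raises(ValueError, match="grid"):
            summarize_group([a, b])


class TestDefaultWindows:
    @pytest.mark.parametrize(
        "neuron,on_dur", [("AWB", 10.0), ("ASH", 10.0), ("AVA", 5.0), ("AIB", 5.0), ("RIM", 5.0)]
    )
    def test_window_durations(self, neuron, on_dur):
        w = default_windows(neuron)
        assert w.on_duration == on_dur
        assert w.off_duration == on_dur
        assert w.on_offset == 0.0

    def test_ava_late_variant(self):
        w = default_windows("AVA", "ava_late")
        assert (w.on_offset, w.on_duration) == (10.0, 10.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            default_windows("other")

    def test_ava_late_restricted_to_ava(self):
        with pytest.raises(ValueError):
            default_windows("AWB", "ava_late")

    def test_invalid_window_values_rejected(self):
        with pytest.raises(ValueError):
            ResponseWindows(0.0, -1.0, 0.0, 5.0)


def test_quantify_end_to_end():
    tr = step_trace(during=150.0, after=170.0)
    m = quantify(tr)
    assert m.on_response == pytest.approx(50.0)
    assert m.off_response == pytest.approx(20.0)
    assert m.threshold_crossed and m.off_latency == 0.0
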