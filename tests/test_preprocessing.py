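import statistics

import numpy as np
import pytest

from valencecode.preprocess import (
    EventRaster,
    baseline_normalize,
    detect_session_events,
    detect_transients,
    qc_filter_neurons,
    smooth_trace,
)
from valencecode.session import ImagingSession
from valencecode.config import five_odor_task


# -- independent exhaustive-scan oracle for transient detection -------------


def oracle_detect(values, rate, baseline_win_s=20.0, k_sd=3.0, min_len=5,
                  min_baseline=5):
    """Literal list-based implementation of the detection rule.

    A frame is supra-threshold when it strictly exceeds median + k_sd *
    1.4826 * MAD of the sub-threshold frames among the trailing
    baseline-window frames; supra-threshold frames never join the
    baseline; runs strictly longer than min_len are events.
    """
    win = int(round(baseline_win_s * rate))
    baseline = []  # (frame index, value) of sub-threshold frames
    flags = []
    for t in range(len(values)):
        v = float(values[t])
        recent = [val for (i, val) in baseline if i >= t - win]
        if len(recent) >= min_baseline:
            med = statistics.median(recent)
            mad = statistics.median([abs(x - med) for x in recent])
            sd = max(1.4826 * mad, 1e-12 * max(1.0, abs(med)))
            above = v > med + k_sd * sd
        else:
            above = False
        flags.append(above)
        if not above:
            baseline.append((t, v))
    events = []
    t = 0
    while t < len(flags):
        if flags[t]:
            start = t
            while t < len(flags) and flags[t]:
                t += 1
            if t - start > min_len:
                events.append((start, t))
        else:
            t += 1
    return events


def random_trace(rng, n=600):
    """Noise plus occasional inserted bumps of assorted shapes."""
    v = rng.normal(0, 1.0, size=n)
    for _ in range(rng.integers(0, 5)):
        start = int(rng.integers(0, n - 20))
        length = int(rng.integers(2, 15))
        shape = rng.choice(["boxcar", "ramp"])
        amp = rng.uniform(2.0, 10.0)
        bump = np.full(length, amp) if shape == "boxcar" else np.linspace(0, amp, length)
        v[start:start + length] += bump
    return v


class TestBaselineNormalize:
    def make_session(self, traces):
        cfg = five_odor_task(n_days=1, trials_per_type_per_day=1)
        from valencecode.session import Trial
        trials = [Trial(i, s, 1) for i, s in enumerate(cfg.stimulus_set)]
        traces = np.broadcast_to(
            traces, (traces.shape[0], len(trials), cfg.n_frames)
        ).copy()
        return ImagingSession(config=cfg, traces=traces, trials=trials)

    def test_constant_trace_normalizes_to_zero(self):
        s = self.make_session(np.full((1, 1, 30), 10.0))
        norm = baseline_normalize(s)
        np.testing.assert_allclose(norm.values, 0.0)
        assert norm.valid.all()

    def test_known_deviation(self):
        tr = np.full((1, 1, 30), 10.0)
        tr[0, 0, 10] = 15.0
        s = self.make_session(tr)
        norm = baseline_normalize(s)
        assert norm.values[0, 0, 10] == pytest.approx(0.5)  # (15-10)/10

    def test_zero_baseline_flagged_invalid(self):
        tr = np.full((1, 1, 30), 10.0)
        tr[0, :, :5] = 0.0
        s = self.make_session(tr)
        norm = baseline_normalize(s)
        assert not norm.valid[0, 0]
        assert np.isnan(norm.values[0, 0]).all()

    def test_scale_free(self):
        rng = np.random.default_rng(0)
        tr = rng.uniform(5, 15, size=(2, 1, 30))
        s1 = self.make_session(tr)
        s2 = self.make_session(tr * 37.5)
        np.testing.assert_allclose(
            baseline_normalize(s1).values, baseline_normalize(s2).values, rtol=1e-12
        )


class TestSmoothTrace:
    def test_span_one_is_identity(self):
        v = np.random.default_rng(1).normal(size=40)
        np.testing.assert_array_equal(smooth_trace(v, 1), v)

    @pytest.mark.parametrize("span", [3, 5, 7])
    def test_constant_preserved(self, span):
        v = np.full(30, 2.5)
        np.testing.assert_allclose(smooth_trace(v, span), v, atol=1e-12)

    @pytest.mark.parametrize("span", [3, 5, 7])
    def test_linear_ramp_preserved(self, span):
        v = np.linspace(0.0, 3.0, 40)
        np.testing.assert_allclose(smooth_trace(v, span), v, atol=1e-9)

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(10), 4)

    def test_output_length_matches(self):
        v = np.random.default_rng(2).normal(size=17)
        assert smooth_trace(v, 5).shape == v.shape


class TestDetectTransients:
    def test_subthreshold_noise_yields_no_events(self):
        rng = np.random.default_rng(3)
        v = np.clip(rng.normal(0, 1.0, size=400), None, 2.5)
        assert detect_transients(v, 5.0) == []

    def test_boxcar_longer_than_minimum_detected(self):
        v = np.zeros(300)
        v[100:108] = 0.5  # 8 frames
        events = detect_transients(v, 5.0)
        assert events == [(100, 108)]

    def test_boxcar_at_minimum_rejected(self):
        v = np.zeros(300)
        v[100:105] = 0.5  # exactly 5 frames: "longer than 5" fails
        assert detect_transients(v, 5.0) == []

    def test_six_frame_boxcar_accepted(self):
        v = np.zeros(300)
        v[100:106] = 0.5
        assert detect_transients(v, 5.0) == [(100, 106)]

    def test_flat_trace_no_events(self):
        assert detect_transients(np.full(200, 3.7), 5.0) == []

    def test_warmup_frames_never_flagged(self):
        v = np.zeros(100)
        v[1:20] = 5.0  # onset before enough baseline history exists
        events = detect_transients(v, 5.0)
        assert all(start >= 5 for start, _ in events)

    def test_oracle_equivalence_on_random_traces(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            v = random_trace(rng)
            assert detect_transients(v, 5.0) == oracle_detect(v, 5.0)


class TestQcFilter:
    def make_raster(self, counts):
        events = [
            np.array([(10 * i, 10 * i + 7) for i in range(c)], dtype=int).reshape(-1, 2)
            for c in counts
        ]
        return EventRaster(events=events, frames_per_trial=30)

    def test_threshold_boundary(self):
        # fewer than two transients excluded; exactly two passes
        mask = qc_filter_neurons(self.make_raster([0, 1, 2, 5]))
        assert mask.tolist() == [False, False, True, True]

    def test_session_events_match_per_neuron_counts(self, small_population):
        session, _ = small_population
        norm = baseline_normalize(session)
        raster = detect_session_events(session, norm)
        mask = qc_filter_neurons(raster)
        np.testing.assert_array_equal(mask, raster.event_counts >= 2)
        # responsive archetypes produce far more than 2 transients
        truth = small_population[1]
        responsive = [i for i, a in enumerate(truth.archetypes)
                      if a.kind != "nonresponsive"]
        assert raster.event_counts[responsive].min() >= 2
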