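import numpy as np
import pytest

from leverseq import (
    CellSpec,
    TraceMatrix,
    action_locked_peak,
    align_responses,
    compute_dff,
    detect_events,
    event_probability,
    pairwise_correlation,
    spontaneous_epochs,
)
from leverseq.calcium import EventTrain
from leverseq.synth import _transient_kernel


def make_tm(dff_rows, rate=10.0):
    """TraceMatrix whose ΔF/F₀ is exactly the given signal (baseline 100)."""
    dff = np.atleast_2d(np.asarray(dff_rows, dtype=float))
    tm = TraceMatrix(
        cell_ids=[f"c{i}" for i in range(dff.shape[0])],
        sampling_rate_hz=rate,
        raw=100.0 * (1 + dff / 100.0),
    )
    tm.dff = dff
    return tm


class TestComputeDff:
    def test_constant_trace_zero_dff(self):
        tm = TraceMatrix(["c"], 10.0, np.full((1, 1200), 80.0))
        compute_dff(tm)
        np.testing.assert_allclose(tm.dff, 0.0, atol=1e-9)

    def test_doubling_gives_100_percent(self):
        raw = np.full(1200, 50.0)
        raw[600] = 100.0
        tm = TraceMatrix(["c"], 10.0, raw[None, :])
        compute_dff(tm)
        assert tm.dff[0, 600] == pytest.approx(100.0, abs=1.0)

    @pytest.mark.parametrize("method", ["percentile", "poly"])
    def test_recovers_amplitude_under_drift(self, method):
        """Known transients on a multiplicative drift come back within 5%."""
        rate, amp = 10.0, 30.0
        t = np.arange(6000) / rate
        kernel, _ = _transient_kernel(0.1, 0.6, rate)
        signal = np.zeros_like(t)
        for s in range(50, 550, 50):
            signal[s * 10 : s * 10 + len(kernel)] += amp * kernel
        drift = 1 + 0.05 * np.sin(2 * np.pi * t / 600)
        raw = 100.0 * drift * (1 + signal / 100)
        tm = TraceMatrix(["c"], rate, raw[None, :])
        compute_dff(tm, method=method)
        # transient amplitude = peak minus the local pre-transient level
        peaks = [
            tm.dff[0, s * 10 : s * 10 + 20].max() - tm.dff[0, s * 10 - 20 : s * 10 - 5].mean()
            for s in range(50, 550, 50)
        ]
        np.testing.assert_allclose(peaks, amp, rtol=0.05)

    def test_scale_invariance(self):
        """Scaling raw F by a constant leaves ΔF/F₀ unchanged."""
        rng = np.random.default_rng(0)
        raw = 100 + rng.normal(0, 1, (2, 2400)).cumsum(axis=1) * 0.01 + 50
        a = TraceMatrix(["x", "y"], 10.0, raw)
        b = TraceMatrix(["x", "y"], 10.0, 3.7 * raw)
        compute_dff(a)
        compute_dff(b)
        np.testing.assert_allclose(a.dff, b.dff, atol=1e-9)

    def test_unknown_method_rejected(self):
        tm = TraceMatrix(["c"], 10.0, np.full((1, 100), 10.0))
        with pytest.raises(ValueError, match="method"):
            compute_dff(tm, method="nope")


class TestDetectEvents:
    def test_noiseless_single_transient(self):
        rate = 10.0
        kernel, peak_off = _transient_kernel(0.1, 0.6, rate)
        sig = np.zeros(600)
        sig[200 : 200 + len(kernel)] = 20 * kernel
        # tiny dither so the MAD noise scale is nonzero
        rng = np.random.default_rng(1)
        sig += rng.normal(0, 0.01, 600)
        tm = make_tm(sig)
        ev = detect_events(tm)
        assert ev.times[0].size == 1
        assert ev.times[0][0] == pytest.approx(20.0 + peak_off, abs=0.2)

    def test_min_separation_keeps_larger(self):
        rate = 10.0
        sig = np.zeros(600)
        sig[200] = 5.0
        sig[202] = 8.0  # 0.2 s apart
        rng = np.random.default_rng(2)
        sig += rng.normal(0, 0.02, 600)
        tm = make_tm(sig)
        ev = detect_events(tm, min_separation_s=0.5)
        assert ev.times[0].size == 1
        assert ev.amplitudes[0][0] == pytest.approx(8.0, abs=0.3)

    def test_flat_trace_empty(self):
        ev = detect_events(make_tm(np.zeros(500)))
        assert ev.times[0].size == 0

    def test_threshold_monotone(self):
        """Raising the prominence threshold never adds events."""
        rng = np.random.default_rng(3)
        sig = rng.normal(0, 1, 3000)
        sig[::200] += 6
        tm = make_tm(sig)
        counts = [detect_events(tm, min_prominence=p).times[0].size for p in (2.0, 3.5, 5.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_false_positive_rate_on_pure_noise(self):
        """At 5 robust-noise units, pure noise yields < 1 event / 100 s."""
        total_events = total_time = 0
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            tm = make_tm(rng.normal(0, 1.0, 2000))  # 200 s at 10 Hz
            total_events += detect_events(tm, min_prominence=5.0).times[0].size
            total_time += 200
        assert total_events / total_time < 1 / 100


class TestAlignResponses:
    def test_transient_lands_after_anchor(self):
        rate = 10.0
        kernel, peak_off = _transient_kernel(0.1, 0.6, rate)
        sig = np.zeros(1200)
        sig[600 : 600 + len(kernel)] = 10 * kernel
        tm = make_tm(sig)
        out = align_responses(tm, [60.0], pre_s=2, post_s=2)
        assert out.tensor.shape == (1, 1, 40)
        curve = out.tensor[0, 0]
        peak_bin = np.argmax(curve)
        assert out.bin_times[peak_bin] == pytest.approx(peak_off, abs=0.1)

    def test_edge_anchor_dropped(self):
        tm = make_tm(np.zeros(100))  # 10 s
        out = align_responses(tm, [9.0, 5.0], pre_s=2, post_s=5)
        assert out.anchors.tolist() == [5.0]

    def test_shuffled_anchors_flat(self):
        """Circularly shifted anchors give a flat mean curve (within 3 SE)."""
        rng = np.random.default_rng(7)
        rate = 10.0
        kernel, _ = _transient_kernel(0.1, 0.6, rate)
        sig = np.zeros(60000)
        true_anchors = np.arange(100, 5900, 60.0)
        for a in true_anchors:
            i = int(a * rate)
            sig[i : i + len(kernel)] += 20 * kernel
        sig += rng.normal(0, 0.5, sig.size)
        tm = make_tm(sig)
        shifted = (true_anchors + 2000.3) % 5800 + 50
        out = align_responses(tm, np.sort(shifted), pre_s=5, post_s=5)
        curve = out.tensor[:, 0, :].mean(axis=0)
        se = out.tensor[:, 0, :].std(axis=0, ddof=1) / np.sqrt(out.tensor.shape[0])
        grand = curve.mean()
        assert np.mean(np.abs(curve - grand) <= 3 * se) > 0.95


class TestEventProbability:
    def test_deterministic_event_every_trial(self):
        ev = EventTrain(["c"], [np.array([10.1, 20.1, 30.1])], [np.ones(3)])
        curves, edges = event_probability(ev, [10.0, 20.0, 30.0], pre_s=1, post_s=1, bin_s=0.2)
        hot = np.flatnonzero(curves[0] == 1.0)
        assert hot.size == 1
        # the event at +0.1 s lands in the [0.0, 0.2) bin
        assert edges[hot[0]] == pytest.approx(0.0, abs=1e-9)
        assert curves[0].sum() == pytest.approx(1.0)

    def test_fractional_probability(self):
        times = np.array([10.05, 20.05])  # 2 of 4 trials
        ev = EventTrain(["c"], [times], [np.ones(2)])
        curves, _ = event_probability(ev, [10, 20, 30, 40], pre_s=0.5, post_s=0.5, bin_s=0.1)
        assert curves[0].max() == pytest.approx(0.5)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(9)
        ev = EventTrain(["c"], [np.sort(rng.uniform(0, 600, 200))], [np.ones(200)])
        curves, _ = event_probability(ev, rng.uniform(50, 550, 30))
        assert np.all(curves >= 0) and np.all(curves <= 1)


class TestActionLockedPeak:
    def test_identical_statistics_normalize_to_one(self):
        """When spontaneous anchors coincide with action anchors the
        normalized peak is exactly 1."""
        rate = 10.0
        kernel, _ = _transient_kernel(0.1, 0.6, rate)
        rng = np.random.default_rng(21)
        sig = rng.normal(0, 0.5, 24000)
        for i in range(100, 23900, 200):
            sig[i : i + len(kernel)] += 10 * kernel
        tm = make_tm(sig)
        n = 40
        # the deterministic spontaneous grid over one epoch [0, 2400) with a
        # ±5 s window is 5 + (i + 0.5)/n * 2390; anchor the action trials there
        anchors = 5 + (np.arange(n) + 0.5) / n * 2390.0
        aligned = align_responses(tm, anchors, pre_s=5, post_s=5)
        summary = action_locked_peak(tm, aligned, [(0.0, 2400.0)], n_spont_anchors=n)
        assert summary.normalized_peak[0] == pytest.approx(1.0, abs=1e-9)

    def test_doubled_action_amplitude(self, small_session):
        log, gt, tm = small_session
        compute_dff(tm)
        anchors = gt.seq_starts
        aligned = align_responses(tm, anchors, pre_s=2, post_s=3)
        spont = spontaneous_epochs(log.presses, log.duration_s, margin_s=10)
        if not any(b - a > 5 for a, b in spont):
            pytest.skip("session too dense for spontaneous epochs")
        summary = action_locked_peak(tm, aligned, spont)
        # action-locked cells respond at sequences, not in quiet epochs
        assert np.all(summary.normalized_peak > 1.5)


class TestSpontaneousEpochs:
    def test_margins(self):
        epochs = spontaneous_epochs([100.0], 300.0, margin_s=10)
        assert epochs == [(0.0, 90.0), (110.0, 300.0)]

    def test_no_presses(self):
        assert spontaneous_epochs([], 100.0) == [(0.0, 100.0)]


class TestPairwiseCorrelation:
    def test_duplicated_cell(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 2000)
        tm = make_tm(np.vstack([x, x]))
        mat, off = pairwise_correlation(tm, [100.0], window_s=10)
        assert mat[0, 1] == pytest.approx(1.0)

    def test_negated_cell(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 2000)
        tm = make_tm(np.vstack([x, -x]))
        mat, off = pairwise_correlation(tm, [100.0], window_s=10)
        assert mat[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(13)
        tm = make_tm(rng.normal(0, 1, (4, 40000)))
        anchors = np.linspace(100, 3900, 50)
        mat, off = pairwise_correlation(tm, anchors, window_s=10)
        assert abs(off) < 0.05

    def test_matrix_properties(self):
        rng = np.random.default_rng(14)
        tm = make_tm(rng.normal(0, 1, (5, 5000)))
        mat, _ = pairwise_correlation(tm, np.linspace(50, 450, 20), window_s=10)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.all(mat >= -1 - 1e-12) and np.all(mat <= 1 + 1e-12)

    def test_zero_variance_cell_excluded(self):
        rng = np.random.default_rng(15)
        sig = np.vstack([rng.normal(0, 1, 2000), np.zeros(2000), rng.normal(0, 1, 2000)])
        tm = make_tm(sig)
        mat, off = pairwise_correlation(tm, [100.0], window_s=10)
        assert np.isnan(mat[0, 1]) and np.isnan(mat[1, 2])
        assert np.isfinite(off)

    def test_single_cell_rejected(self):
        tm = make_tm(np.zeros((1, 100)))
        with pytest.raises(ValueError):
            pairwise_correlation(tm, [5.0])
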