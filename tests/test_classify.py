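import numpy as np
import pytest

from leverseq import (
    AgentParams,
    CellSpec,
    ScheduleSpec,
    classify_onset,
    compute_dff,
    detect_events,
    duration_latency_association,
    efficiency_activity_association,
    segment_sequences,
    shuffle_baseline,
    simulate_behavior,
    simulate_calcium,
    trial_peak_latency,
)


def make_session(cells, n_seqs=60, seed=0, agent=None):
    sched = ScheduleSpec("TC-FR4", ratio=4, time_limit_s=1.0)
    log, gt = simulate_behavior(sched, agent or AgentParams(n_seqs=n_seqs), seed=seed)
    tm, gt = simulate_calcium(log, gt, cells, seed=seed + 1)
    compute_dff(tm)
    return log, gt, tm


class TestClassifyOnset:
    def test_noiseless_archetypes(self):
        cells = [
            CellSpec("instant", latency_base_s=0.1, latency_jitter_s=0.0, noise_sd=0.2,
                     baseline_drift=0.0, reliability=1.0, spont_rate_hz=0.0),
            CellSpec("delayed", latency_base_s=2.0, duration_coupling=0.0,
                     latency_jitter_s=0.0, noise_sd=0.2, baseline_drift=0.0,
                     reliability=1.0, spont_rate_hz=0.0),
        ]
        log, gt, tm = make_session(cells, seed=3)
        onset = classify_onset(tm, gt.seq_starts, seed=0)
        assert onset.labels == ["instant", "delayed"]

    def test_partition(self):
        cells = [CellSpec("instant"), CellSpec("delayed", latency_base_s=1.5),
                 CellSpec("tiled_pyr", reliability=0.3, response_amp=3.0)]
        log, gt, tm = make_session(cells, seed=5)
        onset = classify_onset(tm, gt.seq_starts, seed=0)
        assert len(onset.labels) == tm.n_cells
        assert set(onset.labels) <= {"instant", "delayed", "unclassified"}

    def test_anchor_independent_cell_unclassified(self):
        """A cell with only random background transients fails the shuffle gate."""
        cells = [
            CellSpec("instant", reliability=0.0, spont_rate_hz=0.05, noise_sd=1.0),
            CellSpec("instant", reliability=0.95),
        ]
        log, gt, tm = make_session(cells, n_seqs=80, seed=7)
        onset = classify_onset(tm, gt.seq_starts, seed=1)
        assert onset.labels[0] == "unclassified"
        assert onset.labels[1] == "instant"


class TestShuffleBaseline:
    def test_determinism(self, small_session):
        log, gt, tm = small_session
        compute_dff(tm)
        m1, lo1, hi1 = shuffle_baseline(tm, gt.seq_starts, n_shuffles=100, seed=5)
        m2, lo2, hi2 = shuffle_baseline(tm, gt.seq_starts, n_shuffles=100, seed=5)
        np.testing.assert_array_equal(hi1, hi2)
        np.testing.assert_array_equal(lo1, lo2)

    def test_locked_cell_exceeds_band(self, small_session):
        log, gt, tm = small_session
        compute_dff(tm)
        from leverseq import align_responses

        aligned = align_responses(tm, gt.seq_starts, pre_s=5, post_s=5)
        curve = aligned.mean_curves()
        _, _, hi = shuffle_baseline(tm, gt.seq_starts, n_shuffles=150, seed=2)
        # instant cell (index 0) rises above the null band near its latency
        near = np.abs(aligned.bin_times) <= 1.0
        assert np.any(curve[0, near] > hi[0, near])

    def test_band_shrinks_with_more_shuffles(self, small_session):
        log, gt, tm = small_session
        compute_dff(tm)
        _, lo1, hi1 = shuffle_baseline(tm, gt.seq_starts, n_shuffles=100, seed=3)
        _, lo2, hi2 = shuffle_baseline(tm, gt.seq_starts, n_shuffles=1000, seed=3)
        # central 95% band estimated from more shuffles is no wider on average
        assert (hi2 - lo2).mean() <= (hi1 - lo1).mean() * 1.1

    def test_too_few_shuffles_rejected(self, small_session):
        log, gt, tm = small_session
        compute_dff(tm)
        with pytest.raises(ValueError):
            shuffle_baseline(tm, gt.seq_starts, n_shuffles=10, seed=0)


class TestTrialPeakLatency:
    def test_injected_event_recovered(self):
        cells = [CellSpec("delayed", latency_base_s=1.2, duration_coupling=0.0,
                          latency_jitter_s=0.0, noise_sd=0.3, reliability=1.0,
                          spont_rate_hz=0.0)]
        log, gt, tm = make_session(cells, n_seqs=20, seed=9)
        events = detect_events(tm)
        seqs = segment_sequences(log)
        from leverseq.synth import _transient_kernel

        _, peak_off = _transient_kernel(0.1, 0.6, tm.sampling_rate_hz)
        lats = [trial_peak_latency(tm, events, s, 0) for s in seqs]
        found = [l for l in lats if l is not None]
        assert len(found) >= 15
        assert np.median(found) == pytest.approx(1.2 + peak_off, abs=0.25)

    def test_absent_when_no_event(self):
        cells = [CellSpec("instant", reliability=0.0, spont_rate_hz=0.0, noise_sd=0.5)]
        log, gt, tm = make_session(cells, n_seqs=10, seed=10)
        events = detect_events(tm)
        seqs = segment_sequences(log)
        assert all(trial_peak_latency(tm, events, s, 0) is None for s in seqs)

    def test_largest_amplitude_wins(self):
        from leverseq.calcium import EventTrain
        from leverseq.sequences import SequenceTrial

        seq = SequenceTrial(0, np.array([100.0, 100.5]), "pause", 104.0)
        ev = EventTrain(["c"], [np.array([101.0, 102.5])], [np.array([5.0, 8.0])])
        tm = None  # not consulted when events exist
        assert trial_peak_latency(tm, ev, seq, 0) == pytest.approx(2.5)


class TestAssociations:
    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        res = duration_latency_association(list(1 + 0.5 * x), list(x))
        assert res.r_squared == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.5)

    def test_absent_latencies_dropped(self):
        lats = [1.0, None, 2.0, None, 3.0]
        durs = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = duration_latency_association(lats, durs)
        assert res.n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            duration_latency_association([1.0, None], [1.0, 2.0])

    def test_coupling_recovered_from_traces(self):
        """Latency = base + 0.5 x duration is recovered by regression on
        detected single-trial peaks."""
        cells = [CellSpec("delayed", latency_base_s=0.8, duration_coupling=0.5,
                          latency_jitter_s=0.3, reliability=0.95)]
        agent = AgentParams(n_seqs=200)
        log, gt, tm = make_session(cells, seed=11, agent=agent)
        events = detect_events(tm)
        seqs = segment_sequences(log)
        keep = [s for s in seqs if 0.8 + 0.5 * s.duration_s < 4.0]  # avoid window truncation
        lats = [trial_peak_latency(tm, events, s, 0) for s in keep]
        res = duration_latency_association(lats, [s.duration_s for s in keep])
        assert res.slope == pytest.approx(0.5, abs=2 * max(res.slope_stderr, 0.02) + 0.05)
        assert res.spearman_rho > 0

    def test_efficiency_activity_degenerate_x(self):
        with pytest.raises(ValueError, match="degenerate"):
            efficiency_activity_association([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_efficiency_activity_positive_when_coupled(self):
        amp_scale = {"fast_confined": 1.6, "slow_confined": 1.0, "slow_elongated": 0.5}
        cells = [CellSpec("instant", class_amp_scale=amp_scale),
                 CellSpec("instant", latency_base_s=-0.1, class_amp_scale=amp_scale)]
        log, gt, tm = make_session(cells, n_seqs=150, seed=13)
        from leverseq import seq_efficiency
        from leverseq.classify import session_normalized_trial_peaks

        seqs = segment_sequences(log)
        effs = np.array(
            [
                seq_efficiency(s.n_presses, s.frequency_hz) if np.isfinite(s.frequency_hz) else np.nan
                for s in seqs
            ]
        )
        anchors = np.array([s.start_s for s in seqs])
        peaks, used = session_normalized_trial_peaks(tm, anchors)
        keep = np.isin(anchors, used)
        res = efficiency_activity_association(effs[keep], peaks)
        assert res.slope > 0
        assert res.slope_p < 0.01
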