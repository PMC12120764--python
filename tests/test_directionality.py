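"""Windowed directional matching, bursts and initiation-side percentages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tunnelmea as tm
from tunnelmea.directionality import (
    build_match_window,
    burst_directionality,
    compute_directionality,
    detect_bursts,
    match_directional_events,
)

FS = 12_500.0
T = 1.0 / FS
EI = tm.ElectrodeId("W1", 0, 0)
EJ = tm.ElectrodeId("W1", 0, 7)


def brute_force_match(ti, tj, window, expected):
    """Independent greedy matcher: full candidate enumeration, same ordering."""
    cands = []
    for a, t_i in enumerate(ti):
        for b, t_j in enumerate(tj):
            lag = t_j - t_i
            if window.delta_min_s - 1e-12 <= lag <= window.delta_max_s + 1e-12:
                cands.append((abs(lag - expected), t_i, t_j, a, b, "A_to_B"))
            if window.delta_min_s - 1e-12 <= -lag <= window.delta_max_s + 1e-12:
                cands.append((abs(-lag - expected), t_i, t_j, a, b, "B_to_A"))
    cands.sort(key=lambda c: (c[0], min(c[1], c[2]), max(c[1], c[2]), c[5]))
    used_i, used_j, out = set(), set(), []
    for _, t_i, t_j, a, b, direction in cands:
        if a in used_i or b in used_j:
            continue
        used_i.add(a)
        used_j.add(b)
        out.append((round(t_i, 9), round(t_j, 9), direction))
    return sorted(out)


class TestBuildMatchWindow:
    def test_short_distance_floor_at_one_sample_period(self):
        w = build_match_window(200.0, (1.0, 5.0), pad_samples=0)
        # 200 um / 5 m/s = 40 us, floored to the 80 us sample period
        assert w.delta_min_s == pytest.approx(80e-6)
        assert w.delta_max_s == pytest.approx(200e-6)

    def test_full_span_window(self):
        w = build_match_window(1400.0, (1.0, 5.0), pad_samples=0)
        assert w.delta_min_s == pytest.approx(280e-6)
        assert w.delta_max_s == pytest.approx(1400e-6)

    def test_pad_widens_both_edges_by_one_sample(self):
        w0 = build_match_window(1400.0, (1.0, 5.0), pad_samples=0)
        w1 = build_match_window(1400.0, (1.0, 5.0), pad_samples=1)
        assert w1.delta_min_s == pytest.approx(w0.delta_min_s - 80e-6)
        assert w1.delta_max_s == pytest.approx(w0.delta_max_s + 80e-6)

    def test_inverted_band_rejected(self):
        with pytest.raises(tm.ParameterError):
            build_match_window(200.0, (5.0, 1.0))


class TestMatchDirectionalEvents:
    WINDOW = build_match_window(200.0, (1.0, 5.0), pad_samples=0)  # [80, 200] us

    def test_lag_inside_window_matches_a_to_b(self, make_train):
        events = match_directional_events(
            make_train([1.0]), make_train([1.0001], col=7), self.WINDOW
        )
        assert len(events) == 1
        assert events[0].direction == "A_to_B"
        assert events[0].lag_s == pytest.approx(100e-6)

    def test_reversed_lag_matches_b_to_a(self, make_train):
        events = match_directional_events(
            make_train([1.0001]), make_train([1.0], col=7), self.WINDOW
        )
        assert [e.direction for e in events] == ["B_to_A"]

    def test_lag_outside_window_matches_nothing(self, make_train):
        events = match_directional_events(
            make_train([1.0]), make_train([1.5], col=7), self.WINDOW
        )
        assert events == []

    @given(
        idx_i=st.lists(st.integers(0, 600), unique=True, max_size=30),
        idx_j=st.lists(st.integers(0, 600), unique=True, max_size=30),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_identical_to_brute_force_greedy_oracle(self, idx_i, idx_j):
        ti = np.sort(np.array(idx_i, dtype=float)) / FS
        tj = np.sort(np.array(idx_j, dtype=float)) / FS
        window = build_match_window(1400.0, (0.5, 5.0), pad_samples=1)
        expected = 1400e-6 / 1.75
        got = match_directional_events(
            tm.SpikeTrain(EI, ti), tm.SpikeTrain(EJ, tj), window, expected
        )
        got_tuples = sorted((round(e.t_i, 9), round(e.t_j, 9), e.direction) for e in got)
        assert got_tuples == brute_force_match(ti, tj, window, expected)

    @given(
        idx_i=st.lists(st.integers(0, 600), unique=True, max_size=30),
        idx_j=st.lists(st.integers(0, 600), unique=True, max_size=30),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_one_to_one_conservation_and_symmetry(self, idx_i, idx_j):
        ti = np.sort(np.array(idx_i, dtype=float)) / FS
        tj = np.sort(np.array(idx_j, dtype=float)) / FS
        window = build_match_window(1400.0, (0.5, 5.0), pad_samples=1)
        fwd = match_directional_events(tm.SpikeTrain(EI, ti), tm.SpikeTrain(EJ, tj), window)
        # one-to-one: cannot match more events than either train has
        assert len(fwd) <= min(len(ti), len(tj))
        # swapping the electrodes (and with them the side labels) swaps directions
        rev = match_directional_events(tm.SpikeTrain(EJ, tj), tm.SpikeTrain(EI, ti), window)
        count = lambda evs, d: sum(e.direction == d for e in evs)
        assert count(fwd, "A_to_B") == count(rev, "B_to_A")
        assert count(fwd, "B_to_A") == count(rev, "A_to_B")


class TestDetectBursts:
    def test_five_fast_spikes_are_one_burst(self, make_train):
        t = make_train(1.0 + 0.05 * np.arange(5))
        (burst,) = detect_bursts(t, max_isi_s=0.1, min_burst_spikes=5)
        assert burst.n_spikes == 5
        assert burst.start_s == pytest.approx(1.0)
        assert burst.end_s == pytest.approx(1.2)

    def test_slow_regular_firing_has_no_bursts(self, make_train):
        assert detect_bursts(make_train(np.arange(30) * 1.0)) == []

    @given(idx=st.lists(st.integers(0, 3000), unique=True, max_size=60))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_run_enumeration(self, idx):
        times = np.sort(np.array(idx, dtype=float)) / FS * 50  # spread out
        t = tm.SpikeTrain.from_times(EI, times)
        got = detect_bursts(t, max_isi_s=0.05, min_burst_spikes=3)
        # oracle: walk the train, accumulate runs
        runs, run = [], []
        for x in times:
            if run and x - run[-1] > 0.05:
                runs.append(run)
                run = []
            run.append(x)
        if run:
            runs.append(run)
        expect = [
            (r[0], r[-1], len(r)) for r in runs if len(r) >= 3
        ]
        assert [(b.start_s, b.end_s, b.n_spikes) for b in got] == expect


class TestBurstDirectionality:
    WINDOW = build_match_window(1400.0, (0.5, 5.0), pad_samples=1)

    def test_propagating_burst_matched_by_onset(self, make_train):
        onsets_i = 1.0 + 0.3 * np.arange(3)
        bursts_i = detect_bursts(
            make_train(np.concatenate([o + 0.02 * np.arange(5) for o in onsets_i])),
            max_isi_s=0.1, min_burst_spikes=5,
        )
        bursts_j = detect_bursts(
            make_train(
                np.concatenate([o + 800e-6 + 0.02 * np.arange(5) for o in onsets_i]),
                col=7,
            ),
            max_isi_s=0.1, min_burst_spikes=5,
        )
        events = burst_directionality(bursts_i, bursts_j, self.WINDOW)
        assert len(events) == 3
        assert all(e.direction == "A_to_B" and e.kind == "burst" for e in events)

    def test_distant_bursts_do_not_match(self, make_train):
        bursts_i = detect_bursts(make_train(1.0 + 0.02 * np.arange(5)))
        bursts_j = detect_bursts(make_train(5.0 + 0.02 * np.arange(5), col=7))
        assert burst_directionality(bursts_i, bursts_j, self.WINDOW) == []


class TestComputeDirectionality:
    def test_eight_two_split_gives_eighty_twenty(self):
        events = [
            tm.DirectionalEvent("c", 0.0, 0.001, "A_to_B") for _ in range(8)
        ] + [tm.DirectionalEvent("c", 0.0, -0.001, "B_to_A") for _ in range(2)]
        s = compute_directionality(events, "channel", "c")
        assert (s.pct_a_to_b, s.pct_b_to_a) == (80.0, 20.0)
        assert s.pct_a_to_b + s.pct_b_to_a == 100.0

    def test_zero_events_is_undefined_not_fifty_fifty(self):
        s = compute_directionality([], "channel", "c")
        assert s.pct_a_to_b is None and s.pct_b_to_a is None

    def test_kind_filter_separates_spikes_from_bursts(self):
        events = [
            tm.DirectionalEvent("c", 0.0, 0.001, "A_to_B", kind="spike"),
            tm.DirectionalEvent("c", 0.0, 0.001, "B_to_A", kind="burst"),
        ]
        assert compute_directionality(events, "channel", "c", kind="spike").total == 1
        assert compute_directionality(events, "channel", "c", kind="burst").total == 1


class TestRecoveryFromSimulation:
    def test_exact_recovery_without_jitter_or_background(self, channel8):
        cfg = tm.SimulationConfig(
            geometry=(channel8,), duration_s=120.0, seed=21,
            rate_a_to_b_hz=1.0, rate_b_to_a_hz=1.0,
            velocity_jitter_frac=0.0, background_rate_hz=0.0,
        )
        rec, truth = tm.simulate_recording(cfg)
        (analysis,) = tm.analyze_recording(rec)
        s = analysis.summary("spike")
        c = truth.spike_counts[channel8.channel_id]
        assert (s.count_a_to_b, s.count_b_to_a) == (c["A"], c["B"])

    def test_recovered_percentage_tracks_truth_with_noise(self, channel8):
        """10 seeds, 10% jitter, 1 Hz background: pooled error < 3 points."""
        got_ab = got_total = truth_ab = truth_total = 0
        for seed in range(10):
            cfg = tm.SimulationConfig(geometry=(channel8,), duration_s=300.0, seed=seed)
            rec, truth = tm.simulate_recording(cfg)
            (analysis,) = tm.analyze_recording(rec)
            s = analysis.summary("spike")
            got_ab += s.count_a_to_b
            got_total += s.total
            c = truth.spike_counts[channel8.channel_id]
            truth_ab += c["A"]
            truth_total += c["A"] + c["B"]
        assert truth_total >= 500
        got_pct = 100.0 * got_ab / got_total
        truth_pct = 100.0 * truth_ab / truth_total
        assert abs(got_pct - truth_pct) < 3.0
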