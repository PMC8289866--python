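"""Cross-correlograms and propagation-signal detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from axocouple.mea_io import ElectrodeMap
from axocouple.propagation import (
    PropagationSignal,
    assign_signal_spike_times,
    detect_propagation_signals,
    latency_stats,
    pairwise_ccg,
    peak_window,
    propagation_ratio,
)
from axocouple.simulate import SimulationConfig, UnitSpec, simulate_recording

from conftest import brute_force_ccg_counts, make_recording, make_train


class TestPairwiseCCG:
    def test_fixed_offset_pairs(self):
        ccg = pairwise_ccg(np.array([0.0, 1.0, 2.0]), np.array([0.0003, 1.0003, 2.0003]))
        assert ccg.n_total == 3
        assert np.allclose(ccg.deltas, 0.3)
        assert ccg.n_ref == 3

    def test_autocorrelogram_pairs_every_spike_with_itself(self):
        t = np.array([0.5, 1.5, 2.5])
        ccg = pairwise_ccg(t, t)
        assert ccg.n_total >= ccg.n_ref

    def test_empty_reference_gives_empty_ccg(self):
        ccg = pairwise_ccg(np.array([]), np.array([1.0, 2.0]))
        assert ccg.n_ref == 0 and ccg.n_total == 0

    def test_poisson_coincidence_rate_matches_expectation(self, rng):
        # independent Poisson trains: E[counts] = r*T*s*window
        T, r, s = 200.0, 3.0, 4.0
        ref = np.sort(rng.uniform(0, T, size=rng.poisson(r * T)))
        tgt = np.sort(rng.uniform(0, T, size=rng.poisson(s * T)))
        ccg = pairwise_ccg(ref, tgt, window=(-2.0, 2.0))
        n_brute, _ = brute_force_ccg_counts(ref, tgt, (-2.0, 2.0))
        assert ccg.n_total == n_brute
        expect = r * T * s * 4e-3
        assert abs(ccg.n_total - expect) < 3 * np.sqrt(expect)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 60), st.integers(1, 60))
    def test_binned_counts_equal_brute_force_all_pairs(self, seed, n_ref, n_tgt):
        rng = np.random.default_rng(seed)
        ref = np.sort(rng.uniform(0, 1.0, size=n_ref))
        tgt = np.sort(rng.uniform(0, 1.0, size=n_tgt))
        ccg = pairwise_ccg(ref, tgt, window=(-2.0, 2.0))
        n_brute, deltas = brute_force_ccg_counts(ref, tgt, (-2.0, 2.0))
        assert ccg.n_total == n_brute
        assert int(ccg.counts.sum()) == len(ccg.deltas)
        assert np.allclose(np.sort(ccg.deltas), deltas)

    def test_deltas_lie_inside_window(self, rng):
        ref = np.sort(rng.uniform(0, 5, 50))
        tgt = np.sort(rng.uniform(0, 5, 80))
        ccg = pairwise_ccg(ref, tgt, window=(-1.5, 1.5))
        assert np.all((ccg.deltas >= -1.5) & (ccg.deltas <= 1.5))


class TestPropagationRatio:
    def test_planted_consistent_delay(self, rng):
        ref = np.sort(rng.uniform(0, 100, 100))
        follow = ref[:40] + 0.0003 + rng.normal(0, 2e-5, 40)
        noise = rng.uniform(0, 100, 30)
        tgt = np.sort(np.concatenate([follow, noise]))
        ratio, delay = propagation_ratio(pairwise_ccg(ref, tgt))
        assert ratio >= 0.4
        assert delay == pytest.approx(0.30, abs=0.02)

    def test_empty_target_gives_zero_ratio(self):
        ratio, _ = propagation_ratio(pairwise_ccg(np.array([1.0]), np.array([])))
        assert ratio == 0.0

    def test_no_reference_spikes_gives_zero_ratio(self):
        ratio, _ = propagation_ratio(pairwise_ccg(np.array([]), np.array([1.0])))
        assert ratio == 0.0

    def test_uniform_null_ratio_far_below_threshold(self, rng):
        # independent equal-rate trains: expected ratio ≈ (0.5/4) * E[counts]/n
        T = 300.0
        ref = np.sort(rng.uniform(0, T, 300))
        tgt = np.sort(rng.uniform(0, T, 300))
        ratio, _ = propagation_ratio(pairwise_ccg(ref, tgt))
        assert ratio < 0.1

    @given(st.integers(0, 2**31 - 1))
    def test_moving_window_max_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref = np.sort(rng.uniform(0, 2.0, 40))
        tgt = np.sort(rng.uniform(0, 2.0, 40))
        ccg = pairwise_ccg(ref, tgt)
        pw = peak_window(ccg, 0.5)
        w = int(round(0.5 / ccg.bin_width))
        brute = max(
            int(ccg.counts[i : i + w].sum()) for i in range(len(ccg.counts) - w + 1)
        )
        assert pw.n_win == brute


def axon_config(seed, n_electrodes=3, rate=2.0, duration=250.0, jitter=0.015):
    emap = ElectrodeMap.grid(2, 3)
    electrodes = tuple(f"A{i+1}" for i in range(n_electrodes))
    delays = tuple(0.3 * i for i in range(n_electrodes))
    unit = UnitSpec("u0", rate, electrodes, delays, jitter_sd_ms=jitter)
    return SimulationConfig(
        duration_s=duration, units=(unit,), background_rate_hz=0.0,
        electrode_map=emap, seed=seed,
    )


class TestDetectPropagationSignals:
    def test_simulated_axon_recovered_exactly(self):
        rec, _ = simulate_recording(axon_config(seed=11, jitter=0.02))
        signals = detect_propagation_signals(rec)
        assert len(signals) == 1
        sig = signals[0]
        assert sig.electrode_labels == ["A1", "A2", "A3"]
        truth = {"A1": 0.0, "A2": 0.3, "A3": 0.6}
        for e, d, _ in sig.electrodes:
            assert d == pytest.approx(truth[e], abs=0.05)

    @pytest.mark.parametrize("seed", range(20))
    def test_independent_electrodes_never_form_a_signal(self, seed):
        rng = np.random.default_rng(seed)
        trains = [
            make_train("A1", np.sort(rng.uniform(0, 300, 300))),
            make_train("A2", np.sort(rng.uniform(0, 300, 300))),
        ]
        rec = make_recording(trains, duration=300.0)
        assert detect_propagation_signals(rec) == []

    def test_single_active_electrode_gives_no_signal(self, rng):
        rec = make_recording(
            [make_train("A1", np.sort(rng.uniform(0, 100, 200)))], duration=100.0
        )
        assert detect_propagation_signals(rec) == []

    def test_directional_consistency(self):
        # the reverse CCG of a detected pair peaks near the negated delay
        rec, _ = simulate_recording(axon_config(seed=5))
        sig = detect_propagation_signals(rec)[0]
        d_ab = sig.delay_of("A2")
        rev = pairwise_ccg(rec.train("A2"), rec.train("A1"))
        _, rev_delay = propagation_ratio(rev)
        assert rev_delay == pytest.approx(-d_ab, abs=0.05)

    def test_emitted_signals_have_sorted_nonnegative_delays(self):
        rec, _ = simulate_recording(axon_config(seed=3))
        for sig in detect_propagation_signals(rec):
            delays = [d for _, d, _ in sig.electrodes]
            assert delays == sorted(delays)
            assert all(d >= 0 for d in delays)


class TestAssignSpikeTimes:
    def make_signal(self, e1="A1", e2="A2"):
        return PropagationSignal(
            "sig", [(e1, 0.0, 2), (e2, 0.3, 2)], anchor_first=e1, anchor_second=e2
        )

    def test_mean_of_co_occurring_pairs(self):
        rec = make_recording(
            [make_train("A1", [1.0000, 2.0000]), make_train("A2", [1.0003, 2.0003])]
        )
        sig = assign_signal_spike_times(self.make_signal(), rec)
        assert np.allclose(sig.spike_times, [1.00015, 2.00015])

    def test_empty_second_anchor_gives_empty_times(self):
        rec = make_recording([make_train("A1", [1.0, 2.0]), make_train("A2", [])])
        with pytest.warns(UserWarning, match="zero co-occurrences"):
            sig = assign_signal_spike_times(self.make_signal(), rec)
        assert sig.n_spikes == 0

    def test_matching_is_one_to_one(self):
        # two e1 spikes near one e2 spike: only one co-occurrence
        rec = make_recording(
            [make_train("A1", [1.0000, 1.0010]), make_train("A2", [1.0004])]
        )
        sig = assign_signal_spike_times(self.make_signal(), rec)
        assert sig.n_spikes == 1

    def test_planted_jittered_latency_statistics(self, rng):
        # ~1000 co-occurrences at 0.305 ms with 0.024 ms jitter: CV ≈ 0.078
        t1 = np.sort(rng.uniform(0, 1000, 1000))
        t2 = np.sort(t1 + 0.305e-3 + rng.normal(0, 0.024e-3, 1000))
        rec = make_recording([make_train("A1", t1), make_train("A2", t2)])
        sig = assign_signal_spike_times(self.make_signal(), rec)
        assert sig.n_spikes == 1000
        # inter-anchor latency statistics of the matched pairs
        stats = latency_stats((t2 - t1) * 1e3)
        assert stats.mean == pytest.approx(0.305, abs=0.005)
        assert stats.cv == pytest.approx(0.078, abs=0.02)


class TestLatencyStats:
    def test_two_point_closed_form(self):
        s = latency_stats([1.0, 3.0])
        assert s.mean == 2.0
        assert s.sd == pytest.approx(np.sqrt(2))
        assert s.cv == pytest.approx(np.sqrt(2) / 2)

    def test_constant_deltas_have_zero_cv(self):
        s = latency_stats([2.0, 2.0, 2.0])
        assert s.sd == 0.0 and s.cv == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            latency_stats([1.0])
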