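"""Coupling CCGs, the v1–v6 acceptance criteria, and the reverse analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from axocouple.coupling import (
    Coupling,
    CouplingCriteria,
    CouplingRejection,
    coupled_spike_amplitudes,
    coupling_ccg,
    detect_all_couplings,
    evaluate_coupling,
    stimulation_coupling,
    upstream_inputs,
)
from axocouple.propagation import (
    assign_signal_spike_times,
    detect_propagation_signals,
    peak_window,
)
from axocouple.simulate import (
    CouplingSpec,
    SimulationConfig,
    UnitSpec,
    benchmark_config,
    coupled_pair_config,
    simulate_recording,
)
from axocouple.mea_io import ElectrodeMap

from conftest import brute_force_ccg_counts, make_recording, make_train


class TestCouplingCCG:
    def test_spike_inside_window_counted(self):
        ccg = coupling_ccg(np.array([1.0]), np.array([1.0024]))
        assert ccg.n_total == 1
        assert ccg.deltas[0] == pytest.approx(2.4)

    def test_spike_before_lower_bound_excluded(self):
        ccg = coupling_ccg(np.array([1.0]), np.array([1.0002]))
        assert ccg.n_total == 0

    def test_poisson_chance_counts_match_oracle(self, rng):
        T, rate = 300.0, 3.0
        ref = np.sort(rng.uniform(0, T, 200))
        tgt = np.sort(rng.uniform(0, T, int(rate * T)))
        ccg = coupling_ccg(ref, tgt)
        n_brute, _ = brute_force_ccg_counts(ref, tgt, (0.5, 10.0))
        assert ccg.n_total == n_brute
        expect = 200 * rate * 9.5e-3
        assert abs(ccg.n_total - expect) < 3 * np.sqrt(expect)


class TestEvaluateCoupling:
    def stim_scenario(self, rng, n_stim=500, n_coupled=393):
        stim = np.arange(n_stim, dtype=float)
        lat = rng.uniform(3.5e-3, 5.4e-3, size=n_coupled)  # < 3 ms spread
        tgt = np.sort(stim[:n_coupled] + lat)
        amps = np.full(tgt.size, -44.0) + rng.normal(0, 2.0, tgt.size)
        return stim, make_train("A7", tgt, np.minimum(amps, -1.0))

    def test_stimulation_worked_example_probability(self, rng):
        # 500 stimulations, 393 coupled spikes -> probability 0.79 (2 d.p.)
        stim, tr = self.stim_scenario(rng)
        res = stimulation_coupling(stim, tr)
        assert isinstance(res, Coupling)
        assert res.n_coupled == 393
        assert round(res.coupling_probability, 2) == 0.79

    def test_low_ratio_rejected_under_v1(self, rng):
        stim, tr = self.stim_scenario(rng, n_stim=500, n_coupled=25)  # ratio 0.05
        ccg = coupling_ccg(stim, tr)
        res = evaluate_coupling(ccg, target_amplitudes=tr.amplitudes)
        assert isinstance(res, CouplingRejection)
        assert "v1" in res.reason

    def test_no_reference_spikes_rejected(self):
        ccg = coupling_ccg(np.array([]), np.array([1.0]))
        res = evaluate_coupling(ccg, target_amplitudes=np.array([-40.0]))
        assert isinstance(res, CouplingRejection)
        assert res.reason == "no reference spikes"

    def test_diffuse_latency_rejected_under_v5(self, rng):
        # target independent of ref at high rate: counts spread over the
        # full 9.5 ms window, sd ≈ 2.74 ms > v5
        ref = np.sort(rng.uniform(0, 100, 200))
        tgt = np.sort(rng.uniform(0, 100, 5000))
        res = evaluate_coupling(
            coupling_ccg(ref, tgt), target_amplitudes=np.full(5000, -30.0)
        )
        assert isinstance(res, CouplingRejection)
        assert "v5" in res.reason or "v2" in res.reason

    def test_latency_outside_window_rejected(self, rng):
        ref = np.arange(200, dtype=float)
        tgt = np.sort(ref + rng.uniform(6e-3, 8e-3, 200))  # mean ~7 ms > v4
        res = evaluate_coupling(
            coupling_ccg(ref, tgt), target_amplitudes=np.full(200, -30.0)
        )
        assert isinstance(res, CouplingRejection)
        assert "v3" in res.reason or "latency" in res.reason

    def test_planted_coupling_recovery_over_seeds(self):
        # p=0.4, latency Normal(2.5, 0.8) truncated to the window
        probs, lats = [], []
        for seed in range(10):
            cfg = coupled_pair_config(
                seed=seed, probability=0.4, latency_mean_ms=2.5, latency_sd_ms=0.8
            )
            rec, truth = simulate_recording(cfg)
            ccg = coupling_ccg(truth.unit_trains["pre"], rec.train("C3"))
            res = evaluate_coupling(ccg, target_amplitudes=rec.train("C3").amplitudes)
            assert isinstance(res, Coupling)
            probs.append(res.coupling_probability)
            lats.append(res.mean_latency_ms)
        assert abs(np.mean(probs) - 0.4) < 0.05
        assert abs(np.mean(lats) - 2.5) < 0.2

    def test_multiunit_electrode_raises_verification_flag(self, rng):
        # amplitude CV above v6 -> flag 1; tight unimodal electrode -> flag 0
        ref = np.arange(100, dtype=float)
        tgt = np.sort(ref + 2.5e-3 + rng.normal(0, 3e-4, 100))
        bimodal = -np.where(rng.random(100) < 0.5, 20.0, 45.0)
        res = evaluate_coupling(coupling_ccg(ref, tgt), target_amplitudes=bimodal)
        assert isinstance(res, Coupling) and res.flag == 1
        tight = np.minimum(rng.normal(-45, 2, 100), -1.0)
        res2 = evaluate_coupling(coupling_ccg(ref, tgt), target_amplitudes=tight)
        assert isinstance(res2, Coupling) and res2.flag == 0

    @given(st.integers(0, 2**31 - 1))
    def test_peak_window_scan_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref = np.sort(rng.uniform(0, 10.0, 30))
        tgt = np.sort(rng.uniform(0, 10.0, 60))
        ccg = coupling_ccg(ref, tgt)
        pw = peak_window(ccg, 3.0)
        w = int(round(3.0 / ccg.bin_width))
        brute = max(
            int(ccg.counts[i : i + w].sum()) for i in range(len(ccg.counts) - w + 1)
        )
        assert pw.n_win == brute

    def test_accepted_couplings_satisfy_criteria_on_recheck(self):
        rec, _ = simulate_recording(benchmark_config(seed=2, duration_s=120))
        signals = [
            assign_signal_spike_times(s, rec) for s in detect_propagation_signals(rec)
        ]
        couplings, _ = detect_all_couplings(signals, rec)
        c = CouplingCriteria()
        assert couplings
        for cp in couplings:
            assert 0 <= cp.coupling_probability <= 1
            assert c.v3 <= cp.mean_latency_ms <= c.v4
            assert cp.n_coupled <= cp.n_ref or cp.coupling_probability == 1.0


class TestDetectAllCouplings:
    def test_planted_couplings_recovered_with_direction(self):
        emap = ElectrodeMap.grid(4, 4)
        units = (
            UnitSpec("a", 2.0, ("A1", "A2"), (0.0, 0.3)),
            UnitSpec("b", 2.0, ("B1", "B2"), (0.0, 0.3)),
            UnitSpec("c", 2.0, ("C1", "C2"), (0.0, 0.3)),
        )
        cfg = SimulationConfig(
            duration_s=300.0,
            units=units,
            couplings=(
                CouplingSpec("a", "c", 0.5, 2.5, 0.5),
                CouplingSpec("b", "c", 0.4, 3.0, 0.5),
            ),
            background_rate_hz=0.0,
            electrode_map=emap,
            seed=8,
        )
        rec, _ = simulate_recording(cfg)
        signals = [
            assign_signal_spike_times(s, rec) for s in detect_propagation_signals(rec)
        ]
        assert len(signals) == 3
        couplings, _ = detect_all_couplings(signals, rec)
        sig_pairs = {
            (c.reference_id, c.target_id) for c in couplings if c.target_kind == "signal"
        }
        assert sig_pairs == {("sig_A1", "sig_C1"), ("sig_B1", "sig_C1")}
        # electrode-level detections point at c's cohort only
        for c in couplings:
            if c.target_kind == "electrode":
                assert c.target_id in {"C1", "C2"}

    def test_single_signal_alone_yields_no_couplings(self, rng):
        t = np.sort(rng.uniform(0, 200, 400))
        rec = make_recording(
            [make_train("A1", t), make_train("A2", np.sort(t + 3e-4))], duration=200.0
        )
        signals = [
            assign_signal_spike_times(s, rec) for s in detect_propagation_signals(rec)
        ]
        assert len(signals) == 1
        couplings, _ = detect_all_couplings(signals, rec)
        assert couplings == []


class TestCoupledSpikeAmplitudes:
    def test_indices_map_to_absolute_amplitudes(self):
        tr = make_train("K3", [0.1, 0.2, 0.3], [-40.0, -20.0, -42.0])
        c = Coupling(
            "sig", "K3", "electrode", 0.5, 2.0, 0.5, 2, 4, 0,
            coupled_spike_indices=np.array([0, 2]),
        )
        assert np.allclose(coupled_spike_amplitudes(c, tr), [40.0, 42.0])

    def test_empty_indices_give_empty_list(self):
        tr = make_train("K3", [0.1], [-40.0])
        c = Coupling("sig", "K3", "electrode", 0.0, 2.0, 0.5, 0, 4, 0)
        assert coupled_spike_amplitudes(c, tr).size == 0

    def test_signal_target_not_applicable(self):
        tr = make_train("K3", [0.1], [-40.0])
        c = Coupling("sig", "sig2", "signal", 0.5, 2.0, 0.5, 2, 4, 0)
        with pytest.raises(ValueError, match="electrode targets"):
            coupled_spike_amplitudes(c, tr)

    def test_bimodal_electrode_coupled_spikes_come_from_coupled_mode(self):
        # follower unit at -45 µV shares its electrode with -20 µV background
        cfg = coupled_pair_config(seed=4, probability=0.6, background_rate_hz=1.0)
        rec, truth = simulate_recording(cfg)
        ccg = coupling_ccg(truth.unit_trains["pre"], rec.train("C3"))
        res = evaluate_coupling(ccg, target_amplitudes=rec.train("C3").amplitudes)
        assert isinstance(res, Coupling)
        amps = coupled_spike_amplitudes(res, rec.train("C3"))
        assert np.median(amps) > 35.0  # drawn from the 45 µV mode


class TestUpstreamInputs:
    def test_every_post_spike_preceded_gives_probability_one(self):
        post = np.array([1.0, 2.0, 3.0])
        res = upstream_inputs(post, {"cand": post - 2e-3})
        assert res[0].probability == 1.0
        assert res[0].mean_latency_ms == pytest.approx(2.0)

    def test_silent_candidate_gives_zero(self):
        res = upstream_inputs(np.array([1.0, 2.0]), {"cand": np.array([])})
        assert res[0].probability == 0.0

    def test_no_post_spikes_is_an_error(self):
        with pytest.raises(ValueError, match="no postsynaptic"):
            upstream_inputs(np.array([]), {"cand": np.array([1.0])})

    def test_at_least_one_counting_matches_brute_force(self, rng):
        T = 200.0
        post = np.sort(rng.uniform(0, T, 300))
        cand = np.sort(
            np.concatenate(
                [post[rng.random(300) < 0.3] - 3e-3, rng.uniform(0, T, 200)]
            )
        )
        res = upstream_inputs(post, {"cand": cand})[0]
        brute = sum(
            1 for t in post if np.any((cand >= t - 10e-3) & (cand <= t - 0.5e-3))
        )
        assert res.probability == pytest.approx(brute / post.size)
        assert abs(res.probability - 0.3) < 0.05 + 0.05  # planted p plus chance
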