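"""STDP, synaptic normalization, intrinsic and structural plasticity."""

import numpy as np
import pytest

from lifsorn.plasticity import (
    IPConfig,
    STDPConfig,
    SNConfig,
    StructuralConfig,
    build_w_total,
    intrinsic_plasticity_step,
    normalize_incoming,
    stdp_on_spike,
    structural_growth,
    structural_pruning,
    synaptic_normalization,
)
from lifsorn.topology import ConnectionProfile, pair_probability_matrix, place_neurons

DT = 0.1


def _single_synapse(w0=10.0):
    W = np.zeros((2, 2))
    adj = np.zeros((2, 2), dtype=bool)
    W[0, 1] = w0
    adj[0, 1] = True
    return W, adj


class TestSTDP:
    def test_potentiation_at_one_time_constant(self):
        # pre at t=0, post at t=15 ms: dw = +A+ e^{-1}
        W, adj = _single_synapse()
        last = np.array([0, -1], dtype=np.int64)  # pre spiked at step 0
        stdp_on_spike(W, adj, last, neuron=1, step=150, config=STDPConfig(), dt_ms=DT)
        assert W[0, 1] - 10.0 == pytest.approx(15.0 * np.exp(-1.0), rel=1e-12)

    def test_depression_at_one_time_constant(self):
        # post at t=0, pre at t=30 ms: dw = -A- e^{-1}
        W, adj = _single_synapse()
        last = np.array([-1, 0], dtype=np.int64)  # post spiked at step 0
        stdp_on_spike(W, adj, last, neuron=0, step=300, config=STDPConfig(), dt_ms=DT)
        assert 10.0 - W[0, 1] == pytest.approx(7.5 * np.exp(-1.0), rel=1e-12)

    def test_partner_without_spike_history_means_no_update(self):
        W, adj = _single_synapse()
        last = np.array([-1, -1], dtype=np.int64)
        stdp_on_spike(W, adj, last, 1, 100, STDPConfig())
        stdp_on_spike(W, adj, last, 0, 100, STDPConfig())
        assert W[0, 1] == 10.0

    def test_depression_clips_weight_at_zero(self):
        W, adj = _single_synapse(w0=1e-4)
        last = np.array([-1, 990], dtype=np.int64)
        stdp_on_spike(W, adj, last, 0, 1000, STDPConfig())
        assert W[0, 1] == 0.0

    def test_potentiation_saturates_at_weight_ceiling(self):
        W, adj = _single_synapse(w0=1.0)
        last = np.array([995, -1], dtype=np.int64)
        stdp_on_spike(W, adj, last, 1, 1000, STDPConfig(w_max=1.5))
        assert W[0, 1] == pytest.approx(1.5)

    def test_new_synapse_ignores_pre_creation_spikes(self):
        W, adj = _single_synapse(w0=1e-4)
        creation = np.zeros((2, 2), dtype=np.int64)
        creation[0, 1] = 500  # synapse created after the partner's spike
        last = np.array([100, -1], dtype=np.int64)
        stdp_on_spike(W, adj, last, 1, 600, STDPConfig(), creation_step=creation)
        assert W[0, 1] == 1e-4  # pre spike predates the synapse
        last = np.array([550, -1], dtype=np.int64)
        stdp_on_spike(W, adj, last, 1, 600, STDPConfig(), creation_step=creation)
        assert W[0, 1] > 1e-4

    def test_disabled_config_is_inert(self):
        W, adj = _single_synapse()
        last = np.array([0, -1], dtype=np.int64)
        stdp_on_spike(W, adj, last, 1, 10, STDPConfig(enabled=False))
        assert W[0, 1] == 10.0

    def test_nearest_neighbour_matches_brute_force_oracle(self, rng):
        """Event-driven updates equal a direct evaluation of the pair sum
        restricted to nearest neighbours, on random spike trains."""
        cfg = STDPConfig()
        for trial in range(5):
            t_pre = np.sort(rng.choice(5000, size=40, replace=False))
            t_post = np.sort(rng.choice(5000, size=40, replace=False))
            # event-driven path
            w0 = 500.0  # large enough that clipping never engages
            W, adj = _single_synapse(w0)
            last = np.full(2, -1, dtype=np.int64)
            steps = sorted(set(t_pre.tolist()) | set(t_post.tolist()))
            for step in steps:
                # simultaneous pre/post spikes pair with the partner's
                # previous spike: all same-step updates see the same memory
                spikers = [n for n, ts in ((0, t_pre), (1, t_post)) if step in ts]
                for neuron in spikers:
                    stdp_on_spike(W, adj, last, neuron, step, cfg)
                for neuron in spikers:
                    last[neuron] = step
            # oracle: each pre spike pairs with the latest strictly earlier
            # post spike, each post spike with the latest strictly earlier pre
            delta = 0.0
            for t in t_post:
                earlier = t_pre[t_pre < t]
                if len(earlier):
                    delta += cfg.a_plus * np.exp(-(t - earlier[-1]) * DT / cfg.tau_plus)
            for t in t_pre:
                earlier = t_post[t_post < t]
                if len(earlier):
                    delta -= cfg.a_minus * np.exp(-(t - earlier[-1]) * DT / cfg.tau_minus)
            assert W[0, 1] == pytest.approx(w0 + delta, abs=1e-9)


class TestSynapticNormalization:
    def test_exact_rescaling_example(self):
        np.testing.assert_allclose(
            synaptic_normalization([1.0, 2.0, 3.0], w_total=12.0, eta_sn=1.0),
            [2.0, 4.0, 6.0],
        )

    def test_identity_cases(self):
        w = np.array([2.0, 4.0])
        np.testing.assert_allclose(synaptic_normalization(w, 6.0, 1.0), w)
        np.testing.assert_allclose(synaptic_normalization(w, 60.0, 0.0), w)

    def test_zero_sum_rejected_scalar_path(self):
        with pytest.raises(ValueError):
            synaptic_normalization([0.0, 0.0], 10.0)

    def test_matrix_form_drives_each_incoming_sum_to_target(self, rng):
        W = rng.uniform(0, 2, size=(30, 30))
        W[:, 5] = 0.0  # neuron with no incoming synapses is skipped
        normalize_incoming(W, w_total=60.0, eta_sn=1.0)
        sums = W.sum(axis=0)
        np.testing.assert_allclose(np.delete(sums, 5), 60.0, rtol=1e-12)
        assert sums[5] == 0.0

    def test_partial_rate_moves_halfway(self):
        W = np.full((4, 1), 1.0)  # sum 4, target 8
        normalize_incoming(W, w_total=8.0, eta_sn=0.5)
        assert W.sum() == pytest.approx(6.0)


class TestIntrinsicPlasticity:
    def test_exact_threshold_increments(self):
        cfg = IPConfig()
        vt = np.zeros(2)
        out = intrinsic_plasticity_step(vt, np.array([True, False]), cfg)
        assert out[0] == pytest.approx(0.1 * (1 - 0.0003), rel=1e-12)
        assert out[1] == pytest.approx(-0.1 * 0.0003, rel=1e-12)

    def test_firing_at_target_rate_gives_zero_mean_drift(self):
        # 3 spikes in 10000 steps (1 s) is exactly the 3 Hz target
        cfg = IPConfig()
        vt = np.zeros(1)
        spiked = np.zeros(1, dtype=bool)
        for step in range(10000):
            spiked[0] = step in (0, 3333, 6666)
            vt = intrinsic_plasticity_step(vt, spiked, cfg)
        assert vt[0] == pytest.approx(0.0, abs=1e-9)

    def test_target_rate_to_per_step_target(self):
        assert IPConfig().h_ip(0.1) == pytest.approx(3e-4)
        with pytest.raises(ValueError):
            IPConfig(target_rate_hz=20000.0).h_ip(1.0)


class TestStructural:
    @staticmethod
    def _arrays(n=30, seed=0):
        layout = place_neurons(n, 0, seed=seed)
        prob = pair_probability_matrix(layout.exc_positions, layout.exc_positions,
                                       ConnectionProfile(60.0), exclude_self=True)
        W = np.zeros((n, n))
        adj = np.zeros((n, n), dtype=bool)
        creation = np.full((n, n), np.nan)
        return W, adj, creation, prob

    def test_growth_inserts_requested_count_at_insertion_strength(self, rng):
        W, adj, creation, prob = self._arrays()
        cfg = StructuralConfig(growth_mean=50.0, growth_sd=0.0)
        i, j = structural_growth(W, adj, creation, prob, 3.0, cfg, rng)
        assert len(i) == 50 == adj.sum()
        assert (W[i, j] == cfg.insertion_strength).all()
        assert (creation[i, j] == 3.0).all()
        assert not (i == j).any()

    def test_negative_growth_draw_inserts_nothing(self):
        # the scaled normal has sd equal to its mean, so negative draws
        # are common; they are clipped to zero insertions
        W, adj, creation, prob = self._arrays()
        cfg = StructuralConfig(growth_mean=50.0, growth_sd=50.0)

        class NegativeDraw:
            def normal(self, mean, sd):
                return -42.0

        i, _ = structural_growth(W, adj, creation, prob, 0.0, cfg, NegativeDraw())
        assert len(i) == 0 and adj.sum() == 0

    def test_growth_only_targets_unconnected_pairs(self, rng):
        W, adj, creation, prob = self._arrays()
        cfg = StructuralConfig(growth_mean=100.0, growth_sd=0.0)
        before = adj.copy()
        for t in range(5):
            i, j = structural_growth(W, adj, creation, prob, float(t), cfg, rng)
            assert not before[i, j].any()
            before = adj.copy()
        # no duplicates accumulated
        assert adj.sum() == 500

    def test_growth_draw_capped_at_available_pairs(self, rng):
        W, adj, creation, prob = self._arrays(n=5)
        cfg = StructuralConfig(growth_mean=1000.0, growth_sd=0.0)
        with pytest.warns(UserWarning, match="available pairs"):
            i, _ = structural_growth(W, adj, creation, prob, 0.0, cfg, rng)
        assert len(i) == 20  # all ordered non-self pairs

    def test_pruning_threshold_and_lifetime_log(self):
        W, adj, creation, _ = self._arrays(n=4)
        cfg = StructuralConfig()
        for (i, j), w in [((0, 1), 1e-7), ((1, 2), 1e-4), ((2, 3), 0.0)]:
            adj[i, j] = True
            W[i, j] = w
            creation[i, j] = 2.0
        log = structural_pruning(W, adj, creation, 5.0, cfg)
        assert sorted(zip(log["source"], log["target"])) == [(0, 1), (2, 3)]
        assert (log["t_create_s"] == 2.0).all() and (log["t_death_s"] == 5.0).all()
        assert adj[1, 2] and not adj[0, 1]  # 1e-4 insertion strength survives

    def test_pruning_empty_table_is_noop(self):
        W, adj, creation, _ = self._arrays(n=4)
        assert len(structural_pruning(W, adj, creation, 1.0, StructuralConfig())) == 0

    def test_insertion_strength_must_exceed_threshold(self):
        with pytest.raises(ValueError):
            StructuralConfig(insertion_strength=1e-7, pruning_threshold=1e-6)


class TestWTotal:
    def test_product_rule(self):
        out = build_w_total(
            {"EE": 0.1, "EI": 0.1, "IE": 0.1, "II": 0.5},
            {"EE": 1.5, "EI": 1.5, "IE": -1.5, "II": -1.5},
            n_exc=400, n_inh=80,
        )
        assert out["EE"] == pytest.approx(0.1 * 1.5 * 400)  # 60 mV
        assert out["EI"] == pytest.approx(60.0)
        assert out["IE"] == pytest.approx(0.1 * 1.5 * 80)
        assert out["II"] == pytest.approx(0.5 * 1.5 * 80)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            build_w_total({"EE": 0.0}, {"EE": 1.5}, 400, 80)
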