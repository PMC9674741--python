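"""Cell/area dynamics: integration, output range, plasticity, regulation."""

import numpy as np
import pytest

from semground import _kernels
from semground.architecture import AREA_INDEX
from semground.dynamics import (
    LearningRule,
    global_inhibition_update,
    hebbian_update,
)
from semground.network import N_AREAS, Network, SimulationError

from conftest import toy_config

RULE = LearningRule(ltp_increment=0.1, ltd_decrement=0.05,
                    pre_threshold=0.2, post_threshold=0.2, w_max=1.0,
                    ltd_hetero_decrement=0.02)


def quiet_network(**overrides) -> Network:
    """Toy network with zero weights and all stochastic/regulatory terms off."""
    cfg = toy_config(noise_baseline=0.0, k_local=0.0, k_global=0.0,
                     adapt_strength=0.0, output_threshold=0.0, **overrides)
    net = Network(cfg, rng=np.random.default_rng(0))
    net.syn_w[:] = 0.0
    return net


class TestIntegration:
    def test_silent_network_stays_silent(self):
        net = quiet_network()
        for _ in range(20):
            net.step(None, baseline_noise=False)
        assert np.all(net.output == 0)
        assert np.all(net.potential == 0)

    def test_constant_input_converges_to_closed_form_fixed_point(self):
        """V follows c * (1 - (1 - 1/tau)^t) and converges to c."""
        c, tau = 0.42, 2.5
        net = quiet_network(tau_e=tau, stim_amplitude=c)
        ext = np.zeros((N_AREAS, net.n_cells))
        ext[0, 0] = c
        rho = 1.0 - 1.0 / tau
        for t in range(1, 40):
            net.step(ext, baseline_noise=False)
            expected = c * (1.0 - rho ** t)
            assert net.potential[0] == pytest.approx(expected, rel=1e-12)
        assert net.potential[0] == pytest.approx(c, rel=1e-3)

    def test_outputs_bounded_under_extreme_input(self):
        net = quiet_network()
        ext = np.full((N_AREAS, net.n_cells), 1e4)
        for _ in range(10):
            net.step(ext, baseline_noise=False)
            assert net.output.min() >= 0.0
            assert net.output.max() <= 1.0

    def test_potential_decays_without_input(self):
        net = quiet_network()
        net.potential[:] = 1.0
        for _ in range(30):
            net.step(None, baseline_noise=False)
        assert np.all(np.abs(net.potential) < 1e-4)

    def test_dimension_mismatch_fails_fast(self):
        net = quiet_network()
        with pytest.raises(ValueError, match="external input shape"):
            net.step(np.zeros((3, 7)))

    def test_non_finite_state_reported_with_area(self):
        net = quiet_network()
        net.potential[net.n_cells + 3] = np.inf  # a cell in the second area
        with pytest.raises(SimulationError, match="AB"):
            net.step(None, baseline_noise=False)


class TestHebbianRule:
    def test_no_activity_no_change(self):
        assert hebbian_update(0.0, 0.0, 0.3, RULE) == 0.3

    def test_ltp_when_both_active(self):
        assert hebbian_update(0.9, 0.9, 0.3, RULE) == pytest.approx(0.4)

    def test_ltp_clamped_at_w_max(self):
        assert hebbian_update(0.9, 0.9, RULE.w_max, RULE) == RULE.w_max

    def test_ltd_pre_only_and_post_only(self):
        assert hebbian_update(0.9, 0.0, 0.3, RULE) == pytest.approx(0.25)
        assert hebbian_update(0.0, 0.9, 0.3, RULE) == pytest.approx(0.28)

    def test_hetero_decrement_defaults_to_homosynaptic(self):
        rule = LearningRule(0.1, 0.05, 0.2, 0.2, 1.0)
        assert rule.ltd_hetero_decrement == 0.05

    def test_ltd_clamped_at_zero(self):
        assert hebbian_update(0.9, 0.0, 0.0, RULE) == 0.0

    def test_threshold_is_strict(self):
        w = hebbian_update(RULE.pre_threshold, RULE.post_threshold, 0.3, RULE)
        assert w == 0.3

    def test_kernel_matches_reference_rule(self, rng):
        """The fused numba kernel and the pure function implement the same
        update on random synapse populations."""
        n = 40
        pre = rng.integers(0, n, 300)
        post = rng.integers(0, n, 300)
        order = np.argsort(pre, kind="stable")
        pre, post = pre[order], post[order]
        w = rng.random(300) * RULE.w_max
        out = rng.random(n)
        expected = np.array([
            hebbian_update(out[p], out[q], wi, RULE)
            for p, q, wi in zip(pre, post, w)])
        indptr_pre = np.concatenate(
            ([0], np.cumsum(np.bincount(pre, minlength=n)))).astype(np.int64)
        syn_order = np.argsort(post, kind="stable").astype(np.int64)
        indptr_post = np.concatenate(
            ([0], np.cumsum(np.bincount(post, minlength=n)))).astype(np.int64)
        w_kernel = w.copy()
        _kernels.hebbian(indptr_pre, post.astype(np.int32), w_kernel,
                         indptr_post, syn_order, pre.astype(np.int32),
                         out, RULE.pre_threshold, RULE.post_threshold,
                         RULE.ltp_increment, RULE.ltd_decrement,
                         RULE.ltd_hetero_decrement, RULE.w_max)
        np.testing.assert_allclose(w_kernel, expected, rtol=1e-12)


class TestGlobalInhibition:
    def test_silent_area_decays_geometrically(self):
        g, tau = 5.0, 8.0
        expected = g
        for _ in range(10):
            g = global_inhibition_update(g, 0.0, gain=1.0, time_constant=tau)
            expected *= 1.0 - 1.0 / tau
            assert g == pytest.approx(expected)

    def test_sustained_activity_fixed_point(self):
        g = 0.0
        for _ in range(300):
            g = global_inhibition_update(g, 10.0, gain=0.5, time_constant=4.0)
        assert g == pytest.approx(5.0, rel=1e-6)

    def test_zero_gain_keeps_signal_zero(self):
        g = 0.0
        for _ in range(10):
            g = global_inhibition_update(g, 100.0, gain=0.0, time_constant=4.0)
        assert g == 0.0

    def test_network_global_inhibition_tracks_summed_output(self):
        cfg = toy_config(noise_baseline=0.0, k_local=0.0, k_global=0.0,
                         adapt_strength=0.0, output_threshold=0.0)
        net = Network(cfg, rng=np.random.default_rng(0))
        net.syn_w[:] = 0.0
        ext = np.zeros((N_AREAS, net.n_cells))
        ext[0, :] = 5.0  # saturate every cell of one area
        for _ in range(200):
            net.step(ext, baseline_noise=False)
        assert net.global_inhibition[0] == pytest.approx(net.n_cells, rel=1e-3)
        assert net.global_inhibition[1] == pytest.approx(0.0, abs=1e-9)


class TestReset:
    def test_reset_clears_state_but_not_weights(self):
        net = Network(toy_config(), rng=np.random.default_rng(1))
        before = net.weight_checksum()
        for _ in range(30):
            net.step(None, learning=True)
        after_training = net.weight_checksum()
        net.reset()
        assert np.all(net.potential == 0)
        assert np.all(net.adaptation == 0)
        assert np.all(net.i_potential == 0)
        assert np.all(net.global_inhibition == 0)
        assert net.weight_checksum() == after_training
        assert after_training != before  # learning did change weights

    def test_reset_then_step_without_input_is_silent(self):
        net = Network(toy_config(noise_baseline=0.0),
                      rng=np.random.default_rng(1))
        for _ in range(10):
            net.step(None)
        net.reset()
        net.step(None, baseline_noise=False)
        assert np.all(net.output == 0)


class TestConservationAndDeterminism:
    def test_weight_bounds_hold_throughout_training(self):
        cfg = toy_config(ltp=0.05, ltd=0.02)
        net = Network(cfg, rng=np.random.default_rng(2))
        ext = np.zeros((N_AREAS, net.n_cells))
        ext[AREA_INDEX["V1"], :12] = cfg.stim_amplitude
        for _ in range(200):
            net.step(ext, learning=True)
            assert net.syn_w.min() >= 0.0
            assert net.syn_w.max() <= cfg.w_max

    def test_identical_seed_gives_bit_identical_trajectory(self):
        runs = []
        for _ in range(2):
            net = Network(toy_config(), rng=np.random.default_rng(99))
            ext = np.zeros((N_AREAS, net.n_cells))
            ext[AREA_INDEX["V1"], :5] = 6.0
            for _ in range(50):
                net.step(ext, learning=True)
            runs.append((net.weight_checksum(), net.potential.copy(),
                         net.output.copy()))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])
        np.testing.assert_array_equal(runs[0][2], runs[1][2])

    def test_noise_only_activity_stays_regulated(self, default_config):
        """With default parameters, baseline noise alone must not ignite
        the network (mean output stays below a runaway threshold)."""
        net = Network(default_config, rng=np.random.default_rng(4))
        means = []
        for _ in range(1000):
            net.step(None, learning=True)
            means.append(net.mean_area_output().mean())
        assert max(means[100:]) < 0.2

    def test_hebbian_sanity_two_area_toy(self):
        """Training one 12-cell pattern strengthens stimulated-pair weights
        above unstimulated pairs (within the stimulated area)."""
        cfg = toy_config()
        net = Network(cfg, rng=np.random.default_rng(5))
        v1 = AREA_INDEX["V1"]
        cells = np.arange(12)
        ext = np.zeros((N_AREAS, net.n_cells))
        ext[v1, cells] = cfg.stim_amplitude
        for _ in range(200):
            for _ in range(cfg.train_stim_steps):
                net.step(ext, learning=True)
            for _ in range(5):
                net.step(None, learning=True)
        flat = cells + v1 * net.n_cells
        in_pattern = (np.isin(net.syn_pre, flat) & np.isin(net.syn_post, flat))
        v1_all = ((net.syn_pre // net.n_cells == v1)
                  & (net.syn_post // net.n_cells == v1))
        out_pattern = v1_all & ~np.isin(net.syn_pre, flat) \
            & ~np.isin(net.syn_post, flat)
        assert in_pattern.sum() > 0
        assert net.syn_w[in_pattern].mean() > 5 * net.syn_w[out_pattern].mean()


class TestCheckpointing:
    def test_save_load_roundtrip_is_bit_stable(self, tmp_path):
        net = Network(toy_config(), rng=np.random.default_rng(6))
        for _ in range(20):
            net.step(None, learning=True)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        back = Network.load(path)
        assert back.weight_checksum() == net.weight_checksum()
        for _ in range(20):
            net.step(None, learning=True)
            back.step(None, learning=True)
        np.testing.assert_array_equal(net.potential, back.potential)
        assert back.weight_checksum() == net.weight_checksum()

    def test_clone_shares_nothing(self):
        net = Network(toy_config(), rng=np.random.default_rng(7))
        twin = net.clone()
        twin.syn_w[:] = 0.123
        assert net.syn_w.max() != 0.123


class TestRunLog:
    def test_logging_cadence_and_columns(self):
        net = quiet_network()
        net.enable_logging(every=5)
        for _ in range(20):
            net.step(None, baseline_noise=False)
        log = net.run_log()
        assert list(log["step"]) == [5, 10, 15, 20]
        assert "mean_out_V1" in log.columns
        assert "global_inh_PB" in log.columns

    def test_invalid_cadence_rejected(self):
        with pytest.raises(ValueError):
            quiet_network().enable_logging(every=0)
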