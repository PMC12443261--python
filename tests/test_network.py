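"""Two-area assembly, stepping, inference and reconstruction."""

import numpy as np
import pytest

from pccolumn.dynamics import DynamicsParams
from pccolumn.microcircuit import CellType
from pccolumn.network import Network, NetworkConfig, assemble_network


class TestAssembly:
    def test_population_sizes_match_architecture(self, motif):
        cfg = NetworkConfig(n_pix=1024, n_rep=784, motif=motif)
        net = assemble_network(cfg, seed=0)
        state = net.state_dict()
        assert state.populations["a1_l4e"].size == 1024
        for tag in ("pe_pos", "pe_neg"):
            for ct in ("e", "pv", "sst", "vip"):
                assert state.populations[f"{tag}_{ct}"].size == 1024
        for pop in ("a2_l4e", "a2_pv", "a2_l5e"):
            assert state.populations[pop].size == 784

    def test_w_shape_and_seeded_determinism(self, motif):
        cfg = NetworkConfig(n_pix=1024, n_rep=784, motif=motif)
        a = assemble_network(cfg, seed=42)
        b = assemble_network(cfg, seed=42)
        assert a.W.shape == (1024, 784)
        np.testing.assert_array_equal(a.W, b.W)
        c = assemble_network(cfg, seed=43)
        assert not np.array_equal(a.W, c.W)

    def test_all_rates_start_at_zero(self, toy_config):
        net = assemble_network(toy_config, seed=0)
        for rates in net.state_dict().populations.values():
            np.testing.assert_array_equal(rates, 0.0)


class TestStep:
    def test_zero_stimulus_zero_state_stays_zero(self, toy_config):
        net = assemble_network(toy_config, seed=0)
        for _ in range(50):
            net.step(np.zeros(net.config.n_pix))
        for rates in net.state_dict().populations.values():
            np.testing.assert_array_equal(rates, 0.0)

    def test_without_feedback_pe_circuits_give_pure_bottom_up_response(self, motif):
        """With W = 0 the top-down term vanishes: each PE motif settles at
        the steady state of an isolated 4-unit motif driven only through its
        bottom-up targets by the matching L4 rate."""
        cfg = NetworkConfig(n_pix=16, n_rep=4, motif=motif)
        net = Network(cfg, motif, W=np.zeros((16, 4)))
        stim = np.linspace(0.2, 1.0, 16)
        for _ in range(3000):
            net.step(stim)
        e = CellType.E.index
        for block, pattern in ((0, motif.input_pos), (1, motif.input_neg)):
            expected = _isolated_pe_response(motif, pattern, stim, net.params)
            np.testing.assert_allclose(net.r_pe[block, e], expected, atol=1e-3)

    def test_single_step_matches_hand_computed_drives(self, motif):
        """One Euler step of a 2-pixel / 2-rep network, computed by hand."""
        cfg = NetworkConfig(n_pix=2, n_rep=2, motif=motif)
        W = np.array([[0.1, 0.2], [0.3, 0.4]])
        net = Network(cfg, motif, W=W.copy())
        # seed a known state
        net.r_l4e[:] = [0.5, 0.25]
        net.r_pe[0, 0] = [0.2, 0.1]   # PE+ E
        net.r_pe[1, 0] = [0.05, 0.0]  # PE- E
        net.r_l5e[:] = [1.0, 0.5]
        net.r_a2_l4e[:] = [0.3, 0.2]
        net.r_a2_pv[:] = [0.1, 0.1]
        p = net.params
        a = p.dt / p.tau_exc
        td = W @ np.array([1.0, 0.5])
        bu = np.array([0.5, 0.25])
        base = net.motif.conn.adj * np.array([1.0, -1, -1, -1])[:, None]
        bu_v, td_v = motif.input_pos.bu_vector, motif.input_pos.td_vector
        # expected PE+ E drive for pixel 0: internal + bu + td contributions
        internal = base[:, 0] @ net.r_pe[0, :, 0]
        drive_e0 = internal + bu_v[0] * bu[0] + td_v[0] * td[0]
        expected_pe_e0 = 0.2 + a * (-0.2 + max(drive_e0, 0.0))
        # expected A2 L4 E drive: W^T pe+ - pv
        a2drive = W.T @ np.array([0.2, 0.1]) - np.array([0.1, 0.1])
        expected_a2 = np.array([0.3, 0.2]) + a * (
            -np.array([0.3, 0.2]) + np.maximum(a2drive, 0.0)
        )
        # expected L5: relay of A2 L4 E
        expected_l5 = np.array([1.0, 0.5]) + a * (-np.array([1.0, 0.5]) + np.array([0.3, 0.2]))
        net.step(bu_stim := np.array([0.7, 0.9]))
        assert net.r_pe[0, 0, 0] == pytest.approx(expected_pe_e0, rel=1e-12)
        np.testing.assert_allclose(net.r_a2_l4e, expected_a2, rtol=1e-12)
        np.testing.assert_allclose(net.r_l5e, expected_l5, rtol=1e-12)
        # L4 E moves toward the stimulus
        np.testing.assert_allclose(
            net.r_l4e, bu + a * (-bu + bu_stim), rtol=1e-12
        )

    def test_faithful_relay_tracks_l4e(self, trained_toy, toy_dataset):
        """L5 E is a unit-gain low-pass relay of L4 E, so over any window
        long against tau their mean rates agree (even on a rhythmic run)."""
        net, _ = trained_toy
        net = net.copy()
        net.reset_state()
        trace, _ = net.run(toy_dataset[0], 2.0)
        l4 = trace["a2_l4e"][-500:].mean()
        l5 = trace["rep"][-500:].mean()
        assert l5 == pytest.approx(l4, rel=0.05)

    def test_shared_w_object_serves_both_pathways(self, toy_config):
        net = assemble_network(toy_config, seed=0)
        net.W[:] = 0.0
        net.r_l5e[:] = 1.0
        assert np.all(net.prediction() == 0.0)  # feedback reads the same W


class TestInfer:
    def test_zero_duration_returns_empty_trace_and_leaves_state(self, toy_config):
        net = assemble_network(toy_config, seed=0)
        trace, state = net.infer(np.zeros(net.config.n_pix), 0.0)
        assert trace.t.size == 0
        assert state.t == 0.0

    def test_trained_network_reduces_errors_within_presentation(
        self, trained_toy, toy_dataset
    ):
        net, _ = trained_toy
        net = net.copy()
        net.reset_state()
        trace, _ = net.infer(toy_dataset[0], 2.0)
        x = trace["pe_pos_e"]
        onset_peak = x[:350].max()
        assert x[-500:].mean() < onset_peak  # settles below the onset transient
        assert x[-500:].mean() < x[150:350].mean()

    def test_divergence_time_reported(self, motif):
        cfg = NetworkConfig(
            n_pix=16, n_rep=4, motif=motif, dynamics=DynamicsParams(rate_cap=0.05)
        )
        net = assemble_network(cfg, seed=0)
        net.run(np.ones(16), 0.5)
        assert net.diverged_at is not None


class TestReconstruct:
    def test_zero_representation_gives_black_image(self, toy_config):
        net = assemble_network(toy_config, seed=0)
        np.testing.assert_array_equal(net.reconstruct(), 0.0)

    def test_basis_vector_through_identity_gives_single_pixel(self, motif):
        cfg = NetworkConfig(n_pix=4, n_rep=4, motif=motif)
        net = Network(cfg, motif, W=np.eye(4))
        net.r_l5e[:] = [0.0, 1.0, 0.0, 0.0]
        np.testing.assert_array_equal(net.reconstruct(), [0.0, 1.0, 0.0, 0.0])

    def test_clipped_to_unit_interval(self, motif):
        cfg = NetworkConfig(n_pix=4, n_rep=4, motif=motif)
        net = Network(cfg, motif, W=5.0 * np.eye(4))
        net.r_l5e[:] = 1.0
        assert net.reconstruct().max() <= 1.0

    def test_trained_reconstruction_beats_zero_image(self, trained_toy, toy_dataset):
        from pccolumn.metrics import mse

        net, _ = trained_toy
        net = net.copy()
        net.reset_state()
        net.run(toy_dataset[0], 2.0)
        target = toy_dataset[0].pixels
        assert mse(net.reconstruct(), target) < mse(np.zeros_like(target), target)


class TestClamps:
    def test_clamped_population_reads_zero_at_every_step(self, trained_toy, toy_dataset):
        from pccolumn.protocols import silence_celltype

        net, _ = trained_toy
        net = silence_celltype(net, "SST")
        net.reset_state()
        trace, _ = net.run(toy_dataset[0], 0.3)
        np.testing.assert_array_equal(trace["pe_pos_sst"], 0.0)
        np.testing.assert_array_equal(trace["pe_neg_sst"], 0.0)


def _isolated_pe_response(motif, pattern, stim, params):
    """Steady PE E rates with no top-down input, one motif per pixel."""
    from pccolumn.dynamics import run_to_convergence
    from pccolumn.microcircuit import build_motif_weights

    W = build_motif_weights(motif.conn).T
    out = np.empty(stim.size)
    for i, x in enumerate(stim):
        res = run_to_convergence(W, x * pattern.bu_vector, params, t_max=5.0)
        out[i] = res.state.rates[0]
    return out
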