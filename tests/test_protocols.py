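"""Oddball, silencing, feedback scaling, omission and sweeps."""

import numpy as np
import pytest

from pccolumn.metrics import classify_dynamics, mse
from pccolumn.protocols import (
    ProtocolConfig,
    run_oddball,
    run_omission,
    scale_feedback,
    silence_celltype,
)


@pytest.fixture(scope="module")
def oddball_cfg():
    return ProtocolConfig(n_stimuli=6, deviant_pos=4, present_dur=1.0, isi=0.1)


def _silenced_trace(net, label, stim, duration=2.0):
    run_net = net.copy() if label == "control" else silence_celltype(net, label)
    run_net.reset_state()
    trace, _ = run_net.run(stim, duration)
    return run_net, trace


class TestSilencing:
    def test_silencing_e_rejected(self, trained_toy):
        net, _ = trained_toy
        with pytest.raises(ValueError, match="excitatory"):
            silence_celltype(net, "E")

    def test_vip_clamp_abolishes_negative_error_channel(self, trained_toy, toy_dataset):
        """Without VIP disinhibition the SST pathway fully suppresses the
        negative-error E cells."""
        net, _ = trained_toy
        _, trace = _silenced_trace(net, "VIP", toy_dataset[0])
        assert trace["pe_neg_e"][-500:].mean() < 1e-3
        assert classify_dynamics(trace, "pe_neg_e") == "silent"

    def test_sst_clamp_yields_largest_undamped_oscillation(self, trained_toy, toy_dataset):
        """Removing SST removes the strongest damping element: the error
        circuits oscillate persistently with far larger amplitude than the
        control run."""
        from scipy.signal import detrend

        net, _ = trained_toy
        _, ctrl = _silenced_trace(net, "control", toy_dataset[0])
        _, sst = _silenced_trace(net, "SST", toy_dataset[0])
        assert classify_dynamics(sst, "pe_pos_e") == "sustained"
        var_ctrl = float(np.var(detrend(ctrl["pe_pos_e"][500:])))
        var_sst = float(np.var(detrend(sst["pe_pos_e"][500:])))
        assert var_sst > 3 * var_ctrl

    def test_pv_clamp_elevates_rates_and_degrades_error_coding(
        self, trained_toy, toy_dataset
    ):
        """Without PV inhibition both error populations settle at elevated,
        nearly identical rates: the signed error signal is lost and the
        reconstruction degrades."""
        net, _ = trained_toy
        stim = toy_dataset[0]
        ctrl_net, ctrl = _silenced_trace(net, "control", stim)
        pv_net, pv = _silenced_trace(net, "PV", stim)
        assert pv["pe_pos_e"][-500:].mean() > 2 * ctrl["pe_pos_e"][-500:].mean()
        pos, neg = pv["pe_pos_e"][-1], pv["pe_neg_e"][-1]
        assert pos == pytest.approx(neg, rel=0.05)  # channels indistinguishable
        assert mse(pv_net.reconstruct(), stim.pixels) > mse(
            ctrl_net.reconstruct(), stim.pixels
        )

    def test_control_rhythm_dominates_near_6hz(self, trained_toy, toy_dataset):
        from pccolumn.metrics import dominant_frequency

        net, _ = trained_toy
        _, ctrl = _silenced_trace(net, "control", toy_dataset[0])
        freq = dominant_frequency(ctrl, "pe_pos_e")
        assert freq is not None and 4.0 < freq < 8.0

    def test_phase_relation_between_error_channels_is_stable(
        self, trained_toy, toy_dataset
    ):
        """The two error rhythms keep a fixed phase offset: the lag of the
        PE+/PE- cross-correlation peak is the same in the two halves of the
        presentation (within a couple of integration steps)."""
        from scipy.signal import detrend

        net, _ = trained_toy
        _, ctrl = _silenced_trace(net, "control", toy_dataset[0])

        def peak_lag(a, b):
            a, b = detrend(a), detrend(b)
            lags = np.arange(-100, 101)
            xc = [np.dot(a[100:-100], np.roll(b, k)[100:-100]) for k in lags]
            return lags[int(np.argmax(xc))]

        first = peak_lag(ctrl["pe_pos_e"][500:1250], ctrl["pe_neg_e"][500:1250])
        second = peak_lag(ctrl["pe_pos_e"][1250:], ctrl["pe_neg_e"][1250:])
        assert abs(first - second) <= 3


class TestOddball:
    def test_repeated_standards_reproducible_and_deviant_disrupts(
        self, trained_toy, toy_dataset, oddball_cfg
    ):
        """Identical standards evoke near-identical responses while the
        deviant breaks the pattern in both error circuits."""
        net, _ = trained_toy
        _, peaks = run_oddball(net, toy_dataset[0], toy_dataset[16], oddball_cfg)
        for col in ("peak_pe_pos_e", "peak_pe_neg_e"):
            std = peaks[(peaks["index"] > 0) & (peaks.kind == "standard")][col]
            assert std.std() / std.mean() < 0.05
            dev = peaks[peaks.kind == "deviant"][col].iloc[0]
            assert abs(dev - std.mean()) > 2 * std.std()

    def test_first_stimulus_peak_exceeds_second_standard(
        self, trained_toy, toy_dataset, oddball_cfg
    ):
        """The first stimulus meets a network at rest and evokes the
        largest transient; later standards meet a non-zero state."""
        net, _ = trained_toy
        _, peaks = run_oddball(net, toy_dataset[0], toy_dataset[16], oddball_cfg)
        assert peaks["peak_pe_pos_e"].iloc[0] > peaks["peak_pe_pos_e"].iloc[1]

    def test_deviant_position_validated(self, trained_toy, toy_dataset):
        net, _ = trained_toy
        with pytest.raises(ValueError, match="standards"):
            run_oddball(
                net,
                toy_dataset[0],
                toy_dataset[16],
                ProtocolConfig(n_stimuli=6, deviant_pos=1, present_dur=0.5, isi=0.1),
            )


class TestFeedbackScaling:
    def test_unit_factor_reproduces_control_traces(self, trained_toy, toy_dataset):
        net, _ = trained_toy
        a = net.copy()
        b = scale_feedback(net, 1.0)
        for n in (a, b):
            n.reset_state()
        ta, _ = a.run(toy_dataset[0], 0.5)
        tb, _ = b.run(toy_dataset[0], 0.5)
        np.testing.assert_array_equal(ta["pe_pos_e"], tb["pe_pos_e"])

    def test_reduced_feedback_lowers_oscillatory_power(self, trained_toy, toy_dataset):
        from scipy.signal import detrend

        net, _ = trained_toy
        power = {}
        for factor in (1.0, 0.7):
            run_net = scale_feedback(net, factor)
            run_net.reset_state()
            trace, _ = run_net.run(toy_dataset[0], 2.0)
            power[factor] = float(np.var(detrend(trace["pe_pos_e"][200:])))
        assert power[0.7] < power[1.0]

    def test_zero_feedback_equals_pure_bottom_up_response(self, trained_toy, toy_dataset):
        """With the feedback pathway off, the PE circuits see only bottom-up
        drive, so their traces match a network with no inter-area weights at
        all (whose top-down term is identically zero)."""
        net, _ = trained_toy
        a = scale_feedback(net, 0.0)
        a.reset_state()
        ta, _ = a.run(toy_dataset[0], 1.0)
        b = net.copy()
        b.W = np.zeros_like(b.W)
        b.reset_state()
        tb, _ = b.run(toy_dataset[0], 1.0)
        for name in ("pe_neg_e", "pe_pos_e"):
            np.testing.assert_allclose(ta[name], tb[name], atol=1e-12)

    def test_invalid_factor_rejected(self, trained_toy):
        net, _ = trained_toy
        with pytest.raises(ValueError, match="factor"):
            scale_feedback(net, 1.5)


class TestOmission:
    def test_omitted_stimulus_leaves_only_transient_carryover(
        self, trained_toy, toy_dataset
    ):
        """Without bottom-up input the error circuits carry over activity
        from the preceding stimulus for a few time constants and then fall
        silent — state does not persist through an omitted slot, while a
        driven slot sustains activity throughout."""
        net, _ = trained_toy
        cfg = ProtocolConfig(n_stimuli=6, deviant_pos=4, present_dur=1.0, isi=0.02)
        trace, _ = run_omission(scale_feedback(net, 0.7), toy_dataset[0], cfg)
        period = cfg.present_dur + cfg.isi
        t0 = cfg.deviant_pos * period
        omission = (trace.t > t0 + 0.2) & (trace.t <= t0 + period)
        driven = (trace.t > 2 * period + 0.2) & (trace.t <= 3 * period - cfg.isi)
        assert trace["pe_pos_e"][omission].max() < 1e-4
        assert trace["pe_pos_e"][driven].min() > 0.01

    def test_omission_peak_below_standard_peaks(self, trained_toy, toy_dataset):
        """The omission window holds no driven response: its peak is far
        below the response to an actual stimulus."""
        net, _ = trained_toy
        cfg = ProtocolConfig(n_stimuli=6, deviant_pos=4, present_dur=1.0, isi=0.02)
        _, peaks = run_omission(net, toy_dataset[0], cfg)
        om = peaks[peaks.kind == "omission"].iloc[0]
        std = peaks[peaks.kind == "standard"]["peak_pe_pos_e"].mean()
        assert om["peak_pe_pos_e"] < 0.5 * std


class TestNoiseSweep:
    def test_zero_sigma_input_metrics_are_perfect(self, trained_toy, toy_dataset):
        from pccolumn.protocols import noise_robustness_sweep

        net, _ = trained_toy
        table = noise_robustness_sweep(
            net, toy_dataset[:2], [0.0], "external", seeds=[0]
        )
        assert table["mse_input"].iloc[0] == 0.0
        assert table["ssim_input"].iloc[0] == pytest.approx(1.0)

    def test_external_noise_denoising_range_exists(self, trained_toy, toy_dataset):
        from pccolumn.protocols import noise_robustness_sweep

        net, _ = trained_toy
        table = noise_robustness_sweep(
            net, toy_dataset[:3], [0.1, 0.2, 0.3], "external", seeds=[0, 1]
        )
        assert (table["ssim_recon"] > table["ssim_input"]).any()

    def test_internal_noise_degrades_gracefully(self, trained_toy, toy_dataset):
        from pccolumn.protocols import noise_robustness_sweep

        net, _ = trained_toy
        table = noise_robustness_sweep(
            net, toy_dataset[:2], [0.0, 0.08, 0.16], "internal", seeds=[0, 1]
        )
        s = table["ssim_recon"].to_numpy()
        assert s[0] >= s[-1] - 0.05  # non-increasing trend up to jitter
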