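"""In-silico experimental protocols built on the trained network.

Covers the oddball (mismatch) paradigm, optogenetics-style interneuron
silencing, feedback down-scaling (a coarse proxy for anaesthetic reduction
of top-down drive), stimulus omission, noise-robustness sweeps and the
oscillation-frequency versus membrane-time-constant sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import SimulationTrace, dominant_frequency, mse, ssim
from .microcircuit import CellType
from .network import Network
from .stimuli import Stimulus, add_external_noise, jitter_internal_weights

__all__ = [
    "ProtocolConfig",
    "run_oddball",
    "silence_celltype",
    "scale_feedback",
    "run_omission",
    "noise_robustness_sweep",
    "tau_sweep",
]


@dataclass
class ProtocolConfig:
    """Stimulus schedule shared by the sequence protocols.

    ``n_stimuli`` standards are presented for ``present_dur`` seconds each,
    separated by blank inter-stimulus intervals of ``isi`` seconds; at most
    one position holds a deviant (or an omission).  The ratio
    isi / tau_exc controls how much network state survives between stimuli
    and thereby the size of the mismatch effect.
    """

    present_dur: float = 2.0
    isi: float = 0.2
    n_stimuli: int = 8
    deviant_pos: int | None = None
    silenced: frozenset = field(default_factory=frozenset)
    feedback_scale: float = 1.0
    tau_grid: tuple = (0.010, 0.015, 0.020, 0.030, 0.040)
    noise_grid: tuple = (0.0, 0.05, 0.1, 0.2, 0.3)

    def __post_init__(self) -> None:
        if self.present_dur <= 0 or self.isi <= 0:
            raise ValueError("durations must be positive")
        if self.deviant_pos is not None and not 0 <= self.deviant_pos < self.n_stimuli:
            raise ValueError("deviant position must lie within the sequence")


def silence_celltype(network: Network, celltype, *, include_a2_pv: bool = False) -> Network:
    """Clamp one interneuron type to zero rate in both PE motif arrays.

    Returns a modified copy; the clamp persists for all subsequent steps.
    ``include_a2_pv`` optionally extends a PV clamp to the representation
    circuit's L4 PV population (off by default).  Silencing E is rejected.
    """
    ct = celltype if isinstance(celltype, CellType) else CellType(str(celltype))
    if ct is CellType.E:
        raise ValueError("silencing excitatory cells is not supported")
    net = network.copy()
    net.clamped = net.clamped | {ct}
    net.clamp_a2_pv = include_a2_pv
    return net


def scale_feedback(network: Network, factor: float) -> Network:
    """Scale the L5 -> L2/3 feedback pathway; feedforward is untouched."""
    if not 0.0 <= factor <= 1.0:
        raise ValueError("factor must lie in [0, 1]")
    net = network.copy()
    net.feedback_scale = factor
    return net


def _concat_traces(traces: list[SimulationTrace]) -> SimulationTrace:
    t = np.concatenate([tr.t for tr in traces])
    series = {
        k: np.concatenate([tr.series[k] for tr in traces]) for k in traces[0].series
    }
    return SimulationTrace(t, series)


def _run_sequence(network: Network, stimuli: list, present_dur: float, isi: float):
    """Present stimuli sequentially with blank ISIs; state carries over.

    Returns the concatenated trace plus (onset, offset) windows, each
    running from one stimulus onset to the next (so the window includes the
    trailing ISI, matching how peak responses are read from the trace).
    """
    blank = np.zeros(network.config.n_pix)
    traces, windows = [], []
    for stim in stimuli:
        onset = network.t
        tr, _ = network.run(stim, present_dur)
        traces.append(tr)
        tr, _ = network.run(blank, isi)
        traces.append(tr)
        windows.append((onset, network.t))
    return _concat_traces(traces), windows


def _window_peaks(trace: SimulationTrace, windows, names=("pe_pos_e", "pe_neg_e")):
    rows = []
    for i, (t0, t1) in enumerate(windows):
        sel = (trace.t > t0) & (trace.t <= t1)
        rows.append({"index": i} | {f"peak_{n}": float(trace[n][sel].max()) for n in names})
    return pd.DataFrame(rows)


def run_oddball(
    network: Network,
    standard: Stimulus,
    deviant: Stimulus,
    config: ProtocolConfig,
) -> tuple[SimulationTrace, pd.DataFrame]:
    """Oddball paradigm: repeated standards with one deviant.

    The network (ideally pre-trained on the standard's stimulus class, so
    the deviant is genuinely unpredicted) is presented ``n_stimuli``
    stimuli; position ``config.deviant_pos`` holds the deviant.  Returns the
    full trace and a per-stimulus table of peak mean PE+/PE- E rates with a
    ``kind`` column marking the deviant.
    """
    if config.deviant_pos is None:
        raise ValueError("config.deviant_pos must be set for an oddball run")
    if config.deviant_pos < 3:
        raise ValueError("need at least 3 standards before the deviant")
    net = network.copy()
    net.reset_state()
    seq = [standard] * config.n_stimuli
    seq[config.deviant_pos] = deviant
    trace, windows = _run_sequence(net, seq, config.present_dur, config.isi)
    peaks = _window_peaks(trace, windows)
    peaks["kind"] = ["deviant" if i == config.deviant_pos else "standard" for i in peaks["index"]]
    return trace, peaks


def run_omission(
    network: Network,
    standard: Stimulus,
    config: ProtocolConfig,
) -> tuple[SimulationTrace, pd.DataFrame]:
    """Omission paradigm: one sequence slot is replaced by a blank screen.

    With a prediction established by the preceding standards, the missing
    input violates the expectation from the top-down side only, so mismatch
    activity should arise mainly in the negative-PE circuit.  Returns the
    trace and the per-stimulus peak table (omitted slot marked).
    """
    if config.deviant_pos is None:
        raise ValueError("config.deviant_pos marks the omitted slot")
    net = network.copy()
    net.reset_state()
    blank = Stimulus(np.zeros(network.config.n_pix))
    seq = [standard] * config.n_stimuli
    seq[config.deviant_pos] = blank
    trace, windows = _run_sequence(net, seq, config.present_dur, config.isi)
    peaks = _window_peaks(trace, windows)
    peaks["kind"] = ["omission" if i == config.deviant_pos else "standard" for i in peaks["index"]]
    return trace, peaks


def noise_robustness_sweep(
    network: Network,
    dataset: list,
    noise_grid,
    mode: str,
    seeds,
    *,
    present_dur: float = 2.0,
) -> pd.DataFrame:
    """Reconstruction quality under external (pixel) or internal (synaptic)
    noise.

    For every noise SD the metrics are averaged over the dataset and over
    ``seeds``; internal mode jitters a fresh copy of the pristine weights
    for each (sigma, seed), so noise never accumulates.  Input-side metrics
    (noisy vs original) are reported alongside reconstruction-side metrics
    (reconstruction vs original); in internal mode the input is clean, so
    the input-side columns equal their noiseless values.
    """
    if mode not in ("external", "internal"):
        raise ValueError("mode must be 'external' or 'internal'")
    rows = []
    for sigma in noise_grid:
        stats = {k: [] for k in ("mse_input", "mse_recon", "ssim_input", "ssim_recon")}
        for seed in seeds:
            net = network if mode == "external" else jitter_internal_weights(network, sigma, seed)
            for i, stim in enumerate(dataset):
                shown = (
                    add_external_noise(stim, sigma, seed * 10007 + i)
                    if mode == "external"
                    else stim
                )
                run_net = net.copy()
                run_net.reset_state()
                run_net.run(shown, present_dur)
                recon = run_net.reconstruct()
                stats["mse_input"].append(mse(shown.pixels, stim.pixels))
                stats["ssim_input"].append(ssim(shown.pixels, stim.pixels))
                stats["mse_recon"].append(mse(recon, stim.pixels))
                stats["ssim_recon"].append(ssim(recon, stim.pixels))
        rows.append({"sigma": sigma} | {k: float(np.mean(v)) for k, v in stats.items()})
    return pd.DataFrame(rows)


def tau_sweep(
    network: Network,
    tau_grid,
    stimulus: Stimulus,
    *,
    duration: float = 2.0,
) -> pd.DataFrame:
    """Dominant PE+ rhythm frequency as a function of the membrane time
    constant.

    Steady states of the rate equation are independent of tau, so a single
    (typically trained) network serves the whole grid: for each tau the same
    weights are re-run with tau_exc = tau_inh = tau and the Euler step
    rescaled to tau/20, with plasticity frozen.  Traces with no detectable
    rhythm are recorded as missing, not raised.
    """
    rows = []
    for tau in tau_grid:
        net = network.with_dynamics(network.params.with_tau(tau))
        net.reset_state()
        trace, _ = net.run(stimulus, duration)
        freq = dominant_frequency(trace, "pe_pos_e")
        rows.append({"tau": tau, "frequency": np.nan if freq is None else freq})
    return pd.DataFrame(rows)
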