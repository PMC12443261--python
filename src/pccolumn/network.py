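"""Assembly and simulation of the two-area predictive-coding hierarchy.

Area 1 holds one L4 E cell per pixel and, in L2/3, one positive and one
negative prediction-error (PE) motif per pixel, wired one-to-one from L4.
Area 2 holds the representation circuit: L4 E and L4 PV in a one-to-one
recurrent loop, and L5 E cells that faithfully relay L4 E activity.  A
single dense plastic matrix W (n_pix x n_rep) carries the top-down
prediction ``W @ r_L5E`` to the td-targets of both PE motif arrays, and its
transpose carries the feedforward error signals: the PE+ E rates excite
Area-2 L4 E and the PE- E rates excite Area-2 L4 PV, so the recurrent
E <-> PV pair integrates the signed error.

All populations evolve by the same leaky rectified-linear rate equation;
the wiring is strictly columnar (no lateral input between pixels) apart
from the dense inter-area projections.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DynamicsParams
from .metrics import SimulationTrace
from .microcircuit import CELL_ORDER, CellType, MotifSpec, RepCircuitSpec, build_motif_weights
from .stimuli import Stimulus

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "Network",
    "assemble_network",
    "step_network",
    "infer",
    "reconstruct",
    "TRACE_SERIES",
]

#: Population names recorded in every simulation trace (mean rates).
TRACE_SERIES = (
    "rep",
    "pe_pos_e", "pe_pos_pv", "pe_pos_sst", "pe_pos_vip",
    "pe_neg_e", "pe_neg_pv", "pe_neg_sst", "pe_neg_vip",
    "a2_l4e", "a2_pv",
)

_E = CellType.E.index


@dataclass
class NetworkConfig:
    """Sizes and couplings of the hierarchy.

    ``w_init_scale`` is the upper bound of the uniform inter-area weight
    initialisation; the default ``2/sqrt(n_pix*n_rep)`` gives the rank-one
    mean mode of the feedforward-feedback loop unit gain at initialisation
    and top-down predictions of order the pixel range, independent of
    network size.
    """

    n_pix: int = 1024
    n_rep: int = 784
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    motif: MotifSpec | None = None
    feedback_scale: float = 1.0
    w_init_scale: float | None = None

    def __post_init__(self) -> None:
        if self.n_pix <= 0 or self.n_rep <= 0:
            raise ValueError("n_pix and n_rep must be positive")
        if not 0.0 <= self.feedback_scale <= 1.0:
            raise ValueError("feedback_scale must lie in [0, 1]")

    @property
    def rep_spec(self) -> RepCircuitSpec:
        return RepCircuitSpec(self.n_rep)

    def default_w_scale(self) -> float:
        if self.w_init_scale is not None:
            return self.w_init_scale
        return 2.0 / np.sqrt(self.n_pix * self.n_rep)


@dataclass
class NetworkState:
    """Snapshot of all population rates plus the active clamp set."""

    t: float
    populations: dict
    clamped: frozenset


class Network:
    """A runnable two-area network: weights, state and the step rule."""

    def __init__(self, config: NetworkConfig, motif: MotifSpec, W: np.ndarray):
        self.config = config
        self.params = config.dynamics
        self.motif = motif
        if W.shape != (config.n_pix, config.n_rep):
            raise ValueError(
                f"W must be {(config.n_pix, config.n_rep)}, got {W.shape}"
            )
        self.W = np.asarray(W, dtype=float)
        self.feedback_scale = config.feedback_scale

        n = config.n_pix
        base = build_motif_weights(motif.conn)  # (source, target)
        # per-instance motif weights so internal jitter can differ per pixel
        self.m_pos = np.broadcast_to(base, (n, 4, 4)).copy()
        self.m_neg = np.broadcast_to(base, (n, 4, 4)).copy()
        self._bu = (motif.input_pos.bu_vector, motif.input_neg.bu_vector)
        self._td = (motif.input_pos.td_vector, motif.input_neg.td_vector)
        m = config.n_rep
        self.w_e_pv = np.ones(m)        # A2 L4 E -> L4 PV
        self.w_pv_e = -np.ones(m)       # A2 L4 PV -> L4 E
        self.w_l4_l5 = np.ones(m)       # A2 L4 E -> L5 E (faithful relay)

        self.clamped: frozenset = frozenset()
        self.clamp_a2_pv = False
        self.diverged_at: float | None = None
        self._tau_cell = np.array(
            [self.params.tau_exc if c is CellType.E else self.params.tau_inh for c in CELL_ORDER]
        )
        self.reset_state()

    # -- state ---------------------------------------------------------

    def reset_state(self) -> None:
        """All rates to zero (the network settles from zero activity)."""
        n, m = self.config.n_pix, self.config.n_rep
        self.r_l4e = np.zeros(n)
        self.r_pe = np.zeros((2, 4, n))  # (circuit: 0 = PE+, 1 = PE-; cell; pixel)
        self.r_a2_l4e = np.zeros(m)
        self.r_a2_pv = np.zeros(m)
        self.r_l5e = np.zeros(m)
        self.rep_readout = None
        self.t = 0.0
        self.diverged_at = None

    def copy(self) -> "Network":
        return _copy.deepcopy(self)

    def with_dynamics(self, dynamics: DynamicsParams) -> "Network":
        """Copy of this network (same weights and state) under different
        integration parameters, e.g. for the frequency-vs-tau sweep."""
        net = self.copy()
        net.params = dynamics
        net.config = NetworkConfig(
            n_pix=self.config.n_pix,
            n_rep=self.config.n_rep,
            dynamics=dynamics,
            motif=self.motif,
            feedback_scale=self.config.feedback_scale,
            w_init_scale=self.config.w_init_scale,
        )
        net._tau_cell = np.array(
            [dynamics.tau_exc if c is CellType.E else dynamics.tau_inh for c in CELL_ORDER]
        )
        return net

    def state_dict(self) -> NetworkState:
        pops = {
            "a1_l4e": self.r_l4e.copy(),
            "a2_l4e": self.r_a2_l4e.copy(),
            "a2_pv": self.r_a2_pv.copy(),
            "a2_l5e": self.r_l5e.copy(),
        }
        for b, tag in enumerate(("pe_pos", "pe_neg")):
            for c in CELL_ORDER:
                pops[f"{tag}_{c.value.lower()}"] = self.r_pe[b, c.index].copy()
        return NetworkState(self.t, pops, self.clamped)

    def motif_weight_arrays(self):
        return [self.m_pos, self.m_neg]

    def rep_weight_arrays(self):
        return [self.w_e_pv, self.w_pv_e, self.w_l4_l5]

    # -- dynamics ------------------------------------------------------

    def prediction(self) -> np.ndarray:
        """Instantaneous top-down prediction W @ r_L5E, unclipped."""
        return self.W @ self.r_l5e

    def reconstruct(self) -> np.ndarray:
        """Predicted image, clipped to the pixel range [0, 1].

        After a presentation (:meth:`run`) the readout uses the L5 rates
        time-averaged over the final quarter of that presentation, so the
        reconstruction does not depend on the phase of any residual
        rhythm; before any presentation it uses the instantaneous rates.
        """
        rep = self.r_l5e if self.rep_readout is None else self.rep_readout
        return np.clip(self.W @ rep, 0.0, 1.0)

    def _apply_clamps(self) -> None:
        for ct in self.clamped:
            self.r_pe[:, ct.index, :] = 0.0
        if self.clamp_a2_pv and CellType.PV in self.clamped:
            self.r_a2_pv[:] = 0.0

    def step(self, stimulus: np.ndarray) -> None:
        """One forward-Euler step of every population."""
        p = self.params
        dt = p.dt
        td = self.feedback_scale * self.prediction()
        bu = self.r_l4e

        pe_drive = np.empty_like(self.r_pe)
        for b in range(2):
            internal = np.einsum("isk,si->ki", (self.m_pos, self.m_neg)[b], self.r_pe[b])
            pe_drive[b] = internal + self._bu[b][:, None] * bu + self._td[b][:, None] * td

        a2_l4e_drive = self.W.T @ self.r_pe[0, _E] + self.w_pv_e * self.r_a2_pv
        a2_pv_drive = self.W.T @ self.r_pe[1, _E] + self.w_e_pv * self.r_a2_l4e
        l5e_drive = self.w_l4_l5 * self.r_a2_l4e

        relu = lambda x: np.maximum(x, 0.0)  # noqa: E731
        coef = dt / self._tau_cell
        self.r_l4e += (dt / p.tau_exc) * (-self.r_l4e + relu(np.asarray(stimulus, dtype=float)))
        self.r_pe += coef[None, :, None] * (-self.r_pe + relu(pe_drive))
        self.r_a2_l4e += (dt / p.tau_exc) * (-self.r_a2_l4e + relu(a2_l4e_drive))
        self.r_a2_pv += (dt / p.tau_inh) * (-self.r_a2_pv + relu(a2_pv_drive))
        self.r_l5e += (dt / p.tau_exc) * (-self.r_l5e + relu(l5e_drive))
        self._apply_clamps()
        self.t += dt

        cap = p.rate_cap
        if self.diverged_at is None and (
            self.r_pe.max(initial=0.0) > cap
            or self.r_a2_l4e.max(initial=0.0) > cap
            or self.r_a2_pv.max(initial=0.0) > cap
            or self.r_l5e.max(initial=0.0) > cap
        ):
            self.diverged_at = self.t
        # keep runaway trajectories finite so traces remain analysable
        lid = 10.0 * cap
        for arr in (self.r_pe, self.r_a2_l4e, self.r_a2_pv, self.r_l5e, self.r_l4e):
            np.clip(arr, 0.0, lid, out=arr)

    def _record(self, rec: dict) -> None:
        rec["rep"].append(self.r_l5e.mean())
        for b, tag in enumerate(("pe_pos", "pe_neg")):
            for c in CELL_ORDER:
                rec[f"{tag}_{c.value.lower()}"].append(self.r_pe[b, c.index].mean())
        rec["a2_l4e"].append(self.r_a2_l4e.mean())
        rec["a2_pv"].append(self.r_a2_pv.mean())

    def run(
        self,
        stimulus,
        duration: float,
        *,
        accumulate: bool = False,
    ):
        """Present a constant stimulus for ``duration`` seconds.

        Returns ``(trace, averages)`` where ``averages`` holds per-unit
        time-averaged rates of the plasticity-relevant populations when
        ``accumulate`` is requested (otherwise ``None``).
        """
        if isinstance(stimulus, Stimulus):
            stimulus = stimulus.pixels
        stimulus = np.asarray(stimulus, dtype=float)
        if stimulus.shape != (self.config.n_pix,):
            raise ValueError(
                f"stimulus length {stimulus.size} does not match n_pix {self.config.n_pix}"
            )
        n_steps = int(round(duration / self.params.dt))
        rec = {name: [] for name in TRACE_SERIES}
        sums = None
        if accumulate:
            sums = {
                "pe_pos_e": np.zeros(self.config.n_pix),
                "pe_neg_e": np.zeros(self.config.n_pix),
                "rep": np.zeros(self.config.n_rep),
            }
        n_tail = max(1, n_steps // 4)
        tail_sum = np.zeros(self.config.n_rep)
        for k in range(n_steps):
            self.step(stimulus)
            self._record(rec)
            if k >= n_steps - n_tail:
                tail_sum += self.r_l5e
            if accumulate:
                sums["pe_pos_e"] += self.r_pe[0, _E]
                sums["pe_neg_e"] += self.r_pe[1, _E]
                sums["rep"] += self.r_l5e
        if n_steps:
            self.rep_readout = tail_sum / n_tail
        t = self.t - self.params.dt * np.arange(n_steps - 1, -1, -1) if n_steps else np.array([])
        trace = SimulationTrace(t, {k: np.array(v) for k, v in rec.items()})
        if accumulate and n_steps:
            sums = {k: v / n_steps for k, v in sums.items()}
        return trace, sums

    def infer(self, image, duration: float = 2.0):
        """Run inference with plasticity frozen; returns (trace, state)."""
        trace, _ = self.run(image, duration)
        return trace, self.state_dict()


def assemble_network(config: NetworkConfig, seed: int) -> Network:
    """Build a network with zero rates and seeded uniform W >= 0."""
    from .microcircuit import default_motif_spec

    motif = config.motif if config.motif is not None else default_motif_spec()
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.0, config.default_w_scale(), size=(config.n_pix, config.n_rep))
    return Network(config, motif, W)


# thin functional aliases matching the operation names used elsewhere

def step_network(network: Network, stimulus) -> Network:
    network.step(np.asarray(stimulus, dtype=float))
    return network


def infer(network: Network, image, duration: float = 2.0):
    return network.infer(image, duration)


def reconstruct(network: Network) -> np.ndarray:
    return network.reconstruct()
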