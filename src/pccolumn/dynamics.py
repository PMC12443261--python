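"""Leaky-integrator rate dynamics with rectified-linear activation.

Every population in the model obeys

    tau_k * dr_i/dt = -r_i + f(sum_j W_ij r_j + I_i),    f = ReLU,

integrated with forward Euler.  The time constant tau_k is shared by all
units of a population (tau_exc for E cells, tau_inh for interneurons); both
default to 20 ms.  Starting from non-negative rates, the rectified drive
keeps every trajectory non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DynamicsParams",
    "PopulationState",
    "ConvergenceResult",
    "relu",
    "euler_step",
    "run_to_convergence",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Integration parameters shared across the model.

    Parameters
    ----------
    tau_exc, tau_inh
        Membrane time constants of excitatory and inhibitory units, in
        seconds.  Both default to 20 ms.
    dt
        Forward-Euler step, in seconds.  Must not exceed one tenth of the
        smallest time constant; the default of 1 ms is tau/20.
    rate_cap
        Ceiling (in rate units) above which a trajectory is flagged as
        divergent instead of being allowed to overflow.
    """

    tau_exc: float = 0.020
    tau_inh: float = 0.020
    dt: float = 0.001
    rate_cap: float = 1e3

    def __post_init__(self) -> None:
        if not (self.tau_exc > 0 and self.tau_inh > 0):
            raise ValueError("time constants must be positive")
        tau_min = min(self.tau_exc, self.tau_inh)
        if not (0 < self.dt <= tau_min / 10):
            raise ValueError(
                f"dt={self.dt} must satisfy 0 < dt <= tau_min/10 = {tau_min / 10}"
            )
        if not self.rate_cap > 0:
            raise ValueError("rate_cap must be positive")

    def with_tau(self, tau: float) -> "DynamicsParams":
        """Return a copy with both time constants set to ``tau`` and the
        step rescaled to tau/20 (used by the frequency-vs-tau sweep)."""
        return replace(self, tau_exc=tau, tau_inh=tau, dt=tau / 20.0)


@dataclass
class PopulationState:
    """Rates of one population at time ``t`` (seconds)."""

    rates: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class ConvergenceResult:
    """Outcome of a steady-state run.

    ``status`` is one of ``"converged"``, ``"diverged"`` (a rate crossed
    ``rate_cap``) or ``"not_converged"`` (t_max reached, e.g. a sustained
    oscillation).  Non-convergence is a meaningful result for the circuit
    search, not an error.
    """

    state: PopulationState
    status: str
    residual: float = field(default=np.nan)

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x); rejects non-finite input naming the index."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(np.ravel(x)))[0])
        raise ValueError(f"non-finite input to relu at flat index {bad}")
    return np.maximum(x, 0.0)


def euler_step(
    state: PopulationState,
    drive: np.ndarray,
    tau: float,
    params: DynamicsParams,
) -> PopulationState:
    """One forward-Euler step of ``tau dr/dt = -r + relu(drive)``."""
    drive = np.asarray(drive, dtype=float)
    if drive.shape != state.rates.shape:
        raise ValueError(
            f"drive shape {drive.shape} does not match rates {state.rates.shape}"
        )
    rates = state.rates + (params.dt / tau) * (-state.rates + relu(drive))
    out = PopulationState(rates=rates, t=state.t + params.dt)
    return out


def is_divergent(rates: np.ndarray, params: DynamicsParams) -> bool:
    """True if any rate exceeds the divergence ceiling."""
    return bool(np.any(np.asarray(rates) > params.rate_cap))


def run_to_convergence(
    weights: np.ndarray,
    drive: np.ndarray,
    params: DynamicsParams,
    *,
    tau: np.ndarray | float | None = None,
    tol: float = 1e-6,
    t_max: float = 2.0,
    r0: np.ndarray | None = None,
) -> ConvergenceResult:
    """Integrate ``tau dr/dt = -r + relu(W r + drive)`` to steady state.

    ``weights`` follows the row-equals-target convention: unit *i* receives
    ``(weights @ r)[i]``.  ``tau`` may be a scalar or per-unit vector
    (defaults to ``params.tau_exc``).  The run stops when the per-step
    residual ``max |relu(W r + drive) - r|`` drops below ``tol``, a rate
    crosses ``params.rate_cap`` (diverged), or ``t_max`` elapses.
    """
    weights = np.asarray(weights, dtype=float)
    drive = np.asarray(drive, dtype=float)
    n = drive.shape[0]
    if weights.shape != (n, n):
        raise ValueError(f"weights must be {n}x{n}, got {weights.shape}")
    if tau is None:
        tau = params.tau_exc
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (n,))
    r = np.zeros(n) if r0 is None else np.asarray(r0, dtype=float).copy()
    t = 0.0
    n_steps = int(round(t_max / params.dt))
    coef = params.dt / tau
    residual = np.inf
    for _ in range(n_steps):
        target = np.maximum(weights @ r + drive, 0.0)
        residual = float(np.max(np.abs(target - r)))
        if residual < tol:
            return ConvergenceResult(PopulationState(r, t), "converged", residual)
        r = r + coef * (target - r)
        t += params.dt
        if np.any(r > params.rate_cap):
            r = np.minimum(r, params.rate_cap)
            return ConvergenceResult(PopulationState(r, t), "diverged", residual)
    target = np.maximum(weights @ r + drive, 0.0)
    residual = float(np.max(np.abs(target - r)))
    if residual < tol:
        return ConvergenceResult(PopulationState(r, t), "converged", residual)
    return ConvergenceResult(PopulationState(r, t), "not_converged", residual)
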