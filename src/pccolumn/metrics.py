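"""Reconstruction metrics and oscillation analysis.

Reconstruction quality is quantified by the pixelwise mean squared error and
by a single global-window structural similarity index

    SSIM = (2 mu_R mu_O + c1)(2 sigma_RO + c2)
           / ((mu_R^2 + mu_O^2 + c1)(sigma_R^2 + sigma_O^2 + c2)),

with stabilisers c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03 and
dynamic range L = 1 for pixels in [0, 1].  Note this is the global form
computed over the whole image, not the common sliding-window variant.

Population-rate traces are analysed through the normalised autocorrelation
of the linearly detrended series: the dominant frequency is the reciprocal
of the mean spacing of significant positive autocorrelation peaks, and the
dynamical class of a trace (damped / sustained / divergent / silent) is read
from terminal rates, trend slope and the decay of successive peak
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SSIMParams",
    "SimulationTrace",
    "mse",
    "ssim",
    "autocorrelation",
    "dominant_frequency",
    "classify_dynamics",
    "phase_portrait",
]


@dataclass(frozen=True)
class SSIMParams:
    k1: float = 0.01
    k2: float = 0.03
    L: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.L) <= 0:
            raise ValueError("k1, k2 and L must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2


@dataclass
class SimulationTrace:
    """Uniformly sampled mean-rate series per population."""

    t: np.ndarray
    series: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for name, v in self.series.items():
            if v.shape != self.t.shape:
                raise ValueError(f"series {name!r} length does not match time vector")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]


def mse(P: np.ndarray, A: np.ndarray) -> float:
    """Mean of squared pixel-by-pixel differences."""
    P = np.asarray(P, dtype=float).ravel()
    A = np.asarray(A, dtype=float).ravel()
    if P.shape != A.shape:
        raise ValueError(f"length mismatch: {P.size} vs {A.size}")
    return float(np.mean((P - A) ** 2))


def ssim(R: np.ndarray, O: np.ndarray, params: SSIMParams = SSIMParams()) -> float:
    """Global-window structural similarity of two equal-length images."""
    R = np.asarray(R, dtype=float).ravel()
    O = np.asarray(O, dtype=float).ravel()
    if R.shape != O.shape:
        raise ValueError(f"length mismatch: {R.size} vs {O.size}")
    if R.size < 2:
        raise ValueError("images must have at least 2 pixels")
    mu_r, mu_o = R.mean(), O.mean()
    var_r, var_o = R.var(), O.var()
    cov = float(np.mean((R - mu_r) * (O - mu_o)))
    num = (2 * mu_r * mu_o + params.c1) * (2 * cov + params.c2)
    den = (mu_r**2 + mu_o**2 + params.c1) * (var_r + var_o + params.c2)
    return float(num / den)


def autocorrelation(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalised autocorrelation of the detrended series, lags 0..max_lag.

    The series is linearly detrended (inference traces carry a decaying
    baseline) and normalised so the lag-0 value is 1.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= 2 * max_lag:
        raise ValueError("series must be longer than twice max_lag")
    x = signal.detrend(x, type="linear")
    var = float(np.dot(x, x)) / x.size
    if var <= 0 or np.isclose(var, 0.0, atol=1e-30):
        raise ValueError("zero-variance series has no autocorrelation")
    # unbiased estimator: the biased form tapers linearly with lag, which
    # would make sustained oscillations look damped
    acf = np.array(
        [np.dot(x[: x.size - k], x[k:]) / (x.size - k) for k in range(max_lag + 1)]
    )
    return acf / var


def _significant_peaks(acf: np.ndarray, n_samples: int):
    """Positive acf peaks exceeding the white-noise bound 3/sqrt(N)."""
    bound = 3.0 / np.sqrt(n_samples)
    peaks, props = signal.find_peaks(acf[1:], height=bound)
    return peaks + 1, props["peak_heights"]


def dominant_frequency(trace: SimulationTrace, name: str) -> float | None:
    """Dominant rhythm of a trace series, in Hz, or ``None`` if absent.

    Estimated as the reciprocal of the mean spacing of significant positive
    autocorrelation peaks — the spacing from lag zero to the first peak
    counts as one interval.  Invariant to affine rescaling of the series.
    """
    x = trace[name]
    if trace.duration < 1.0:
        raise ValueError("trace must cover at least 1 s")
    if np.allclose(x, x[0]):
        return None
    max_lag = (x.size - 1) // 2
    acf = autocorrelation(x, max_lag)
    lags, _ = _significant_peaks(acf, x.size)
    if lags.size == 0:
        return None
    spacing = np.diff(np.concatenate([[0], lags])).mean()
    return float(1.0 / (spacing * trace.dt))


def classify_dynamics(
    trace: SimulationTrace,
    name: str,
    *,
    rate_cap: float = 1e3,
    eps_silent: float = 1e-3,
    delta: float = 0.05,
    transient_frac: float = 0.1,
) -> str:
    """Classify a population-rate trace.

    Returns one of ``"silent"`` (terminal activity below ``eps_silent``),
    ``"divergent"`` (the rate cap was hit, or a persistently rising trend),
    ``"damped"`` (successive autocorrelation peak amplitudes decay by more
    than ``delta`` per cycle, or no rhythm survives on a converging trace)
    or ``"sustained"``.
    """
    x = trace[name]
    n = x.size
    tail = x[int(0.9 * n):]
    if np.max(x) >= rate_cap:
        return "divergent"
    if float(tail.mean()) < eps_silent:
        return "silent"
    # rising-trend test on the post-transient part of the trace
    body = x[int(transient_frac * n):]
    tb = np.arange(body.size) * trace.dt
    slope = float(np.polyfit(tb, body, 1)[0])
    scale = max(float(body.mean()), 1e-12)
    if slope * trace.duration > 0.5 * scale:
        return "divergent"
    acf = autocorrelation(body, (body.size - 1) // 2)
    lags, heights = _significant_peaks(acf, body.size)
    if lags.size == 0:
        return "damped"
    if lags.size == 1:
        return "damped" if heights[0] < 1.0 - delta else "sustained"
    ratios = heights[1:] / heights[:-1]
    return "damped" if np.median(ratios) < 1.0 - delta else "sustained"


def phase_portrait(trace: SimulationTrace, name_a: str, name_b: str):
    """Paired samples (A(t), B(t)) plus the terminal point (putative stable
    focus) for phase-plane inspection."""
    a, b = trace[name_a], trace[name_b]
    return a, b, (float(a[-1]), float(b[-1]))
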