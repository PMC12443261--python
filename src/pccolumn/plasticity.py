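"""Hebbian learning of the inter-area weights with batch-parallel training.

After each 2-s presentation the shared inter-area matrix W is updated from
the coincidence of prediction-error activity in Area 1 and representation
activity in Area 2:

    dW = gamma_w * [ r_E^{PE+} (r^{Rep})^T - r_E^{PE-} (r^{Rep})^T ].

A positive error (prediction too small) strengthens the weights that build
the prediction; a negative error weakens them.  Training is batch-parallel:
every image of a batch is inferred by an independent copy of the network
holding the same pre-batch W, the per-copy updates are averaged, and the
single averaged update is applied before the next batch.  Between
presentations the network views a blank screen long enough (0.2 s, ten
excitatory time constants) that activity decays to rest, so each copy
starts from the zero state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import mse
from .network import Network
from .stimuli import Stimulus

__all__ = ["LearningConfig", "hebbian_delta", "train_batch", "train"]


@dataclass(frozen=True)
class LearningConfig:
    """Training hyper-parameters.

    ``gamma_w`` is the Hebbian learning rate (dimensionless); one pass over
    the dataset presents each image once, and ``n_repeats`` passes are run.
    ``use_time_average`` switches the rates entering the update from the
    final-time rates of the presentation (default) to their time average
    over the presentation, for sensitivity analyses.
    """

    gamma_w: float = 0.5
    batch_size: int = 64
    present_dur: float = 2.0
    blank_dur: float = 0.2
    n_repeats: int = 100
    use_time_average: bool = False

    def __post_init__(self) -> None:
        if self.gamma_w <= 0:
            raise ValueError("gamma_w must be positive")
        if self.present_dur <= 0 or self.blank_dur <= 0:
            raise ValueError("durations must be positive")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")


def hebbian_delta(
    r_pe_pos: np.ndarray,
    r_pe_neg: np.ndarray,
    r_rep: np.ndarray,
    gamma_w: float,
) -> np.ndarray:
    """Weight update gamma_w * (PE+ - PE-) outer r_rep, shape n_pix x n_rep."""
    r_pe_pos = np.asarray(r_pe_pos, dtype=float)
    r_pe_neg = np.asarray(r_pe_neg, dtype=float)
    r_rep = np.asarray(r_rep, dtype=float)
    if r_pe_pos.shape != r_pe_neg.shape:
        raise ValueError(
            f"PE vectors must have equal length, got {r_pe_pos.shape} and {r_pe_neg.shape}"
        )
    return gamma_w * np.outer(r_pe_pos - r_pe_neg, r_rep)


def _copy_rates(network: Network, image, config: LearningConfig):
    """Infer one image in a fresh copy; return the rates entering the rule
    plus the copy's final reconstruction error."""
    net = network.copy()
    net.reset_state()
    trace, averages = net.run(
        image, config.present_dur, accumulate=config.use_time_average
    )
    if net.diverged_at is not None:
        label = getattr(image, "label", None)
        raise RuntimeError(
            f"divergence at t={net.diverged_at:.3f}s while inferring "
            f"image {label!r}; batch aborted"
        )
    if config.use_time_average:
        pe_pos, pe_neg, rep = averages["pe_pos_e"], averages["pe_neg_e"], averages["rep"]
    else:
        pe_pos = net.r_pe[0, 0].copy()
        pe_neg = net.r_pe[1, 0].copy()
        rep = net.r_l5e.copy()
    pixels = image.pixels if isinstance(image, Stimulus) else np.asarray(image)
    err = mse(net.reconstruct(), pixels)
    return pe_pos, pe_neg, rep, err


def train_batch(network: Network, images: list, config: LearningConfig) -> dict:
    """One batch update: per-copy Hebbian deltas averaged, applied once.

    Mutates ``network.W`` in place and returns batch statistics (mean final
    PE rates across copies, mean reconstruction MSE).
    """
    deltas = np.zeros_like(network.W)
    pe_pos_means, pe_neg_means, errs = [], [], []
    for image in images:
        pe_pos, pe_neg, rep, err = _copy_rates(network, image, config)
        deltas += hebbian_delta(pe_pos, pe_neg, rep, config.gamma_w)
        pe_pos_means.append(float(pe_pos.mean()))
        pe_neg_means.append(float(pe_neg.mean()))
        errs.append(err)
    network.W += deltas / len(images)
    return {
        "mean_pe_pos": float(np.mean(pe_pos_means)),
        "mean_pe_neg": float(np.mean(pe_neg_means)),
        "mse": float(np.mean(errs)),
    }


def train(
    network: Network,
    dataset: list,
    config: LearningConfig,
    seed: int,
) -> tuple[Network, pd.DataFrame]:
    """Train on ``dataset`` for ``config.n_repeats`` passes.

    The presentation order is reshuffled every pass with a generator seeded
    by ``seed``, so two runs with the same seed produce identical weight
    histories.  Returns the trained network and a per-batch history table
    (repeat, batch, mean PE+ and PE- rates, reconstruction MSE).
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for repeat in range(config.n_repeats):
        order = rng.permutation(len(dataset))
        for b0 in range(0, len(dataset), config.batch_size):
            batch = [dataset[i] for i in order[b0 : b0 + config.batch_size]]
            stats = train_batch(network, batch, config)
            stats.update(repeat=repeat, batch=b0 // config.batch_size)
            rows.append(stats)
    history = pd.DataFrame(
        rows, columns=["repeat", "batch", "mean_pe_pos", "mean_pe_neg", "mse"]
    )
    return network, history
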