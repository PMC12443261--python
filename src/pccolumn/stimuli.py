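"""Image ingestion, synthetic stimulus generation and the two noise models.

Stimuli are flattened grayscale images with pixel values in [0, 1]; each
pixel drives exactly one L4 E cell of the lower area.  The synthetic
generator emulates naturalistic input statistics at configurable resolution
with three families:

``blobs``
    sums of a few random Gaussian bumps — smooth, spatially correlated
    patterns reminiscent of defocused natural scenes.
``gratings``
    sinusoidal gratings of random orientation, spatial frequency and phase.
``lowrank``
    non-negative combinations of k fixed smooth basis patterns, so the
    dataset is exactly compressible into a latent code of dimension k and
    the pixel->representation compression is learnable by construction.

Two noise models probe robustness: external noise perturbs pixels of the
presented image (one Gaussian draw per presentation, clipped back to
[0, 1]); internal noise jitters every existing within-circuit synapse while
leaving the learned inter-area weights untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "Stimulus",
    "NoiseConfig",
    "load_grayscale_images",
    "synth_dataset",
    "add_external_noise",
    "jitter_internal_weights",
]


@dataclass
class Stimulus:
    """A flattened grayscale image with values in [0, 1]."""

    pixels: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float).ravel()
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def n_pix(self) -> int:
        return self.pixels.size

    @property
    def side(self) -> int:
        side = int(round(np.sqrt(self.n_pix)))
        if side * side != self.n_pix:
            raise ValueError("stimulus is not square")
        return side

    def image(self) -> np.ndarray:
        return self.pixels.reshape(self.side, self.side)


@dataclass(frozen=True)
class NoiseConfig:
    """Standard deviations of the two Gaussian noise sources.

    ``sigma_ext`` perturbs input pixels; ``sigma_int`` jitters within-circuit
    synaptic weights (absolute SD on unit-magnitude synapses, so a 16% noise
    level corresponds to sigma_int = 0.16).
    """

    sigma_ext: float = 0.0
    sigma_int: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_ext < 0 or self.sigma_int < 0:
            raise ValueError("noise SDs must be non-negative")


def load_grayscale_images(path, target_side: int | None = None) -> list[Stimulus]:
    """Load raster image(s) as grayscale stimuli.

    ``path`` may be a single file or a directory (sorted file order).
    Colour images are converted by the per-pixel channel mean, rescaled to
    [0, 1] and flattened row-major; images are resized to
    ``target_side`` x ``target_side`` when requested.
    """
    p = Path(path)
    files = sorted(q for q in p.iterdir() if q.is_file()) if p.is_dir() else [p]
    out = []
    for f in files:
        try:
            with Image.open(f) as im:
                arr = np.asarray(im, dtype=float)
        except Exception as exc:  # noqa: BLE001 - re-raise naming the file
            raise ValueError(f"cannot read image file {f}") from exc
        if arr.ndim == 3:
            arr = arr.mean(axis=2)  # luminance as channel average
        if arr.ndim != 2:
            raise ValueError(f"unsupported image dimensions in {f}: {arr.shape}")
        arr = arr / 255.0
        if target_side is not None and arr.shape != (target_side, target_side):
            im2 = Image.fromarray(np.uint8(np.clip(arr, 0, 1) * 255))
            arr = np.asarray(im2.resize((target_side, target_side)), dtype=float) / 255.0
        out.append(Stimulus(np.clip(arr, 0.0, 1.0).ravel(), label=f.stem))
    return out


def _blob(side: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side] / side
    img = np.zeros((side, side))
    for _ in range(rng.integers(2, 5)):
        cx, cy = rng.uniform(0.15, 0.85, size=2)
        sig = rng.uniform(0.08, 0.25)
        amp = rng.uniform(0.4, 1.0)
        img += amp * np.exp(-(((xx - cx) ** 2) + ((yy - cy) ** 2)) / (2 * sig**2))
    return img / max(img.max(), 1e-12)

def _grating(side: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side] / side
    theta = rng.uniform(0, np.pi)
    freq = rng.uniform(1.0, 4.0)
    phase = rng.uniform(0, 2 * np.pi)
    g = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
    return 0.5 * (g + 1.0)

def lowrank_basis(side: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k fixed smooth non-negative basis patterns, shape (k, side*side)."""
    return np.stack([_blob(side, rng).ravel() for _ in range(k)])


def synth_dataset(
    n: int,
    side: int = 32,
    kind: str = "blobs",
    seed: int = 0,
    *,
    k: int = 4,
) -> list[Stimulus]:
    """Deterministic synthetic dataset of ``n`` stimuli of ``side``^2 pixels.

    For ``kind="lowrank"`` each image is a non-negative combination of ``k``
    fixed basis patterns (normalised so pixels stay in [0, 1]).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out = []
    if kind == "blobs":
        out = [Stimulus(_blob(side, rng).ravel(), label=f"blob{i}") for i in range(n)]
    elif kind == "gratings":
        out = [Stimulus(_grating(side, rng).ravel(), label=f"grating{i}") for i in range(n)]
    elif kind == "lowrank":
        basis = lowrank_basis(side, k, rng)
        for i in range(n):
            coeff = rng.dirichlet(np.ones(k))
            img = coeff @ basis
            # normalise to a naturalistic dynamic range: peak near white
            img = img / max(img.max(), 1e-12) * rng.uniform(0.7, 1.0)
            out.append(Stimulus(np.clip(img, 0.0, 1.0), label=f"lowrank{i}"))
    else:
        raise ValueError(f"unknown stimulus kind: {kind!r}")
    return out


def add_external_noise(stim: Stimulus, sigma_ext: float, seed: int) -> Stimulus:
    """Pixel noise: one i.i.d. Gaussian draw per presentation, then clip."""
    if sigma_ext < 0:
        raise ValueError("sigma_ext must be non-negative")
    if sigma_ext == 0:
        return Stimulus(stim.pixels.copy(), stim.label)
    rng = np.random.default_rng(seed)
    noisy = stim.pixels + rng.normal(0.0, sigma_ext, size=stim.n_pix)
    return Stimulus(np.clip(noisy, 0.0, 1.0), stim.label)


def jitter_internal_weights(network, sigma_int: float, seed: int):
    """Return a copy of ``network`` whose within-circuit synapses carry
    i.i.d. Gaussian jitter.

    Noise is added to every existing synapse of every PE-motif instance and
    to the one-to-one weights of the representation circuit; structural
    zeros stay zero and the learned inter-area matrix W is untouched.
    """
    if sigma_int < 0:
        raise ValueError("sigma_int must be non-negative")
    net = network.copy()
    if sigma_int == 0:
        return net
    rng = np.random.default_rng(seed)
    for arr in net.motif_weight_arrays():  # (n_pix, 4, 4) per PE block
        mask = arr != 0.0
        arr[mask] += rng.normal(0.0, sigma_int, size=int(mask.sum()))
    for arr in net.rep_weight_arrays():  # one-to-one vectors, all nonzero
        arr += rng.normal(0.0, sigma_int, size=arr.shape)
    return net
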