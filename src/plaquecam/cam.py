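"""Gradient-free Score-CAM, SmoothGrad saliency, and jet-overlay rendering.

Score-CAM weights each upsampled activation channel by how much masking
the input with it raises the target-class probability over an all-zero
baseline, then sums the positively weighted channels.  The faster variant
restricts the sum to the few channels with the largest spatial variance.
SmoothGrad averages absolute input-gradients over Gaussian-perturbed
copies of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .image import StandardizedImage
from .model import ActivationStack, ScoringModel
from .labels import class_index


class DegenerateHeatmapError(ValueError):
    """Raised when a degenerate (all-zero) heatmap cannot be visualized."""


@dataclass
class Heatmap:
    """Class-attribution raster in [0, 1] on the model-input grid.

    Non-degenerate maps span exactly [0, 1] after min-max normalization;
    ``degenerate`` flags the all-zero case (every channel weight
    non-positive), the modeled "no visualization possible" failure mode.
    """

    values: np.ndarray
    target_class: str
    degenerate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")
        if not self.degenerate and not (
            np.isclose(self.values.min(), 0) and np.isclose(self.values.max(), 1)
        ):
            raise ValueError("non-degenerate heatmaps must span [0, 1]")


@dataclass
class SaliencyMap:
    """Non-negative averaged |gradient| field on the input grid."""

    values: np.ndarray
    target_class: str
    n_samples: int
    noise_level: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("saliency values must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def select_top_channels(stack: ActivationStack, k: int = 3) -> list[int]:
    """Indices of the k channels with largest spatial variance, descending.

    Stable: ties keep their original channel order.  k past the stack size
    returns all channels in variance order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chans = stack.channels
    if chans.shape[0] == 0:
        raise ValueError("empty activation stack")
    variances = chans.reshape(chans.shape[0], -1).var(axis=1)
    order = np.argsort(-variances, kind="stable")
    return [int(i) for i in order[: min(k, chans.shape[0])]]


def _minmax_01(field: np.ndarray) -> np.ndarray:
    lo, hi = float(field.min()), float(field.max())
    if hi <= lo:  # constant channel: undefined min-max -> all-zero mask
        return np.zeros_like(field)
    return (field - lo) / (hi - lo)


def _upsample(channel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if channel.shape == shape:
        return channel.astype(float)
    return resize(channel.astype(float), shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def score_cam(
    model: ScoringModel,
    image: StandardizedImage,
    target_class: str,
    k: int | None = 3,
) -> Heatmap:
    """Faster Score-CAM over the model's activation stack.

    For each of the top-k variance channels: bilinear-upsample to the
    input grid, min-max normalize to [0, 1], perturb the input by
    element-wise product, and weight the channel by the target-class
    probability of the perturbed input minus that of an all-zero baseline.
    The output is ReLU of the weighted channel sum, min-max normalized;
    if the pre-normalization field is identically zero the heatmap is
    flagged degenerate.  ``k=None`` uses every channel (exhaustive
    Score-CAM).
    """
    stack = model.activations(image)
    n_chan = stack.channels.shape[0]
    idx = select_top_channels(stack, n_chan if k is None else k)
    tgt = class_index(target_class)
    shape = image.pixels.shape
    pixels = np.asarray(image.pixels, dtype=float)

    baseline = StandardizedImage(np.zeros(shape), image.plaque_mask, dict(image.provenance))
    p_base = model.predict_proba(baseline)[tgt]

    field = np.zeros(shape)
    for c in idx:
        norm = _minmax_01(_upsample(stack.channels[c], shape))
        masked = StandardizedImage(norm * pixels, image.plaque_mask, dict(image.provenance))
        weight = model.predict_proba(masked)[tgt] - p_base
        field += weight * norm
    field = np.maximum(field, 0.0)
    if field.max() == 0.0:
        return Heatmap(np.zeros(shape), target_class, degenerate=True)
    return Heatmap(_minmax_01(field), target_class)


def smooth_grad(
    model: ScoringModel,
    image: StandardizedImage,
    target_class: str,
    n: int = 20,
    noise: float = 0.30,
    seed: int = 0,
) -> SaliencyMap:
    """Average of |gradient| over n Gaussian-perturbed copies of the image.

    The noise scale is ``noise * (max - min)`` of the image.  Seeded and
    bit-reproducible; ``n=1, noise=0`` reduces to the plain absolute
    gradient.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if not model.has_gradient:
        raise NotImplementedError("model exposes no gradient capability")
    pixels = np.asarray(image.pixels, dtype=float)
    sigma = noise * float(pixels.max() - pixels.min())
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(pixels)
    for _ in range(n):
        perturbed = pixels if sigma == 0 else np.clip(pixels + rng.normal(0, sigma, pixels.shape), 0, 255)
        noisy = StandardizedImage(perturbed, image.plaque_mask, dict(image.provenance))
        acc += np.abs(model.gradient(noisy, target_class))
    return SaliencyMap(acc / n, target_class, n, noise)


def render_jet_overlay(
    hm: Heatmap,
    image: StandardizedImage,
    restrict_to_plaque: bool = True,
    alpha: float = 0.5,
) -> np.ndarray:
    """Continuous jet coloring alpha-blended over the grayscale image.

    With ``restrict_to_plaque`` the coloring applies only inside the
    plaque mask.  Degenerate heatmaps (or an empty plaque intersection)
    raise :class:`DegenerateHeatmapError` — an explicit "no visualization"
    outcome, never an image of zeros.
    """
    if hm.degenerate:
        raise DegenerateHeatmapError("degenerate heatmap: no visualization possible")
    region = image.plaque_mask if restrict_to_plaque else np.ones_like(image.plaque_mask)
    if not region.any():
        raise DegenerateHeatmapError("empty overlay region: no visualization possible")
    jet = colormaps["jet"](hm.values)[..., :3]  # continuous colormap, RGB in [0,1]
    gray = np.repeat(np.asarray(image.pixels, dtype=float)[..., None] / 255.0, 3, axis=2)
    out = gray.copy()
    out[region] = (1 - alpha) * gray[region] + alpha * jet[region]
    return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)
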