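"""Classifier contract, deterministic band-oracle model, and data split.

The CAM stage only ever needs three capabilities from a classifier —
class probabilities, spatial activations from a designated internal layer,
and (optionally) a per-pixel gradient of the class score.  Freezing a
pretrained backbone and training only a small dense head means downstream
attribution sees exactly this surface, so it is captured here as an
abstract contract.  A handcrafted, fully deterministic band-attending
oracle implements the contract for testing and synthetic studies: its
score is a known function of one composition band's pixel share, so CAM
localization can be checked against generative ground truth.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import block_reduce

from .compositions import BAND_UPPER, COMPOSITIONS
from .image import CANVAS_SHAPE, StandardizedImage
from .labels import ASY, CLASSES, SY, class_index


@dataclass
class ActivationStack:
    """Channels from one internal layer, all sharing a reduced spatial shape."""

    channels: np.ndarray  # (C, h, w)
    layer_name: str = "activations"

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3 or self.channels.shape[0] == 0:
            raise ValueError("activation stack must be a non-empty (C, h, w) array")


class ScoringModel(ABC):
    """The classifier surface the attribution stage relies on.

    ``predict_proba`` returns a probability vector ordered (ASY, SY)
    summing to 1; ``activations`` is deterministic given the image.
    Gradient capability is optional (raise ``NotImplementedError`` when
    absent).
    """

    input_size: tuple = CANVAS_SHAPE  # (rows, cols) = (224, 512)

    @abstractmethod
    def predict_proba(self, image: StandardizedImage) -> np.ndarray:
        ...

    @abstractmethod
    def activations(self, image: StandardizedImage) -> ActivationStack:
        ...

    def gradient(self, image: StandardizedImage, target_class: str) -> np.ndarray:
        raise NotImplementedError("this model exposes no gradient capability")

    @property
    def has_gradient(self) -> bool:
        try:
            cls_method = type(self).gradient
        except AttributeError:
            return False
        return cls_method is not ScoringModel.gradient


#: Intensity at or below the blood reference range ([0, 5] after
#: normalization) is treated as anechoic background, not tissue.
ANECHOIC_FLOOR = 5.0


def _band_bounds(band_index: int) -> tuple[float, float]:
    lo = 0.0 if band_index == 0 else float(BAND_UPPER[band_index - 1])
    return lo, float(BAND_UPPER[band_index])


class BandOracleModel(ScoringModel):
    """Deterministic classifier attending to one grayscale band.

    The class score is a softmax over (a*f, -a*f) where ``f`` is the
    attended band's share of plaque pixels and ``a`` the sharpness, so the
    attended class's probability increases strictly with the band's area.
    Pixels at or below the blood reference intensity (GS <= 5 after
    normalization) count as anechoic background rather than tissue, which
    keeps channel-masked perturbation images (whose background is
    attenuated toward zero) interpretable.

    Activations are computed from the image itself: blurred, plaque-
    restricted indicators of the attended band and of the complementary
    bright (GS > 125) pixels, plus a constant channel, block-averaged onto
    a reduced grid.  The analytic gradient differentiates a smooth
    Gaussian band-membership surrogate (the hard indicator has zero
    derivative almost everywhere).
    """

    def __init__(
        self,
        attend_band: str | int = "bk",
        attend_class: str = SY,
        sharpness: float = 2.0,
        downsample: int = 8,
        blur_sigma: float = 2.0,  # kept below the channel-grid stride
    ):
        if isinstance(attend_band, str):
            attend_band = COMPOSITIONS.index(attend_band.lower())
        if not 0 <= attend_band < 6:
            raise ValueError("attend_band must name one of the six bands")
        if not sharpness > 0:
            raise ValueError("sharpness must be positive")
        self.attend_band = int(attend_band)
        self.attend_class = attend_class
        self.sharpness = float(sharpness)
        self.downsample = int(downsample)
        self.blur_sigma = float(blur_sigma)
        self._attend_idx = class_index(attend_class)

    # -- scoring ---------------------------------------------------------
    def _band_member(self, v: np.ndarray, plaque_mask: np.ndarray) -> np.ndarray:
        lo, hi = _band_bounds(self.attend_band)
        return (v > max(lo, ANECHOIC_FLOOR)) & (v <= hi) & plaque_mask

    def band_fraction(self, image: StandardizedImage) -> float:
        """Share of plaque pixels inside the attended band (anechoic excluded)."""
        v = np.asarray(image.pixels, dtype=float)
        member = self._band_member(v, image.plaque_mask)
        return float(member.sum() / image.plaque_mask.sum())

    def predict_proba(self, image: StandardizedImage) -> np.ndarray:
        z = self.sharpness * self.band_fraction(image)
        p_attend = 1.0 / (1.0 + np.exp(-2.0 * z))  # softmax of (z, -z)
        probs = np.empty(2)
        probs[self._attend_idx] = p_attend
        probs[1 - self._attend_idx] = 1.0 - p_attend
        return probs

    # -- activations -----------------------------------------------------
    def activations(self, image: StandardizedImage) -> ActivationStack:
        v = np.asarray(image.pixels, dtype=float)
        inside = image.plaque_mask
        band = self._band_member(v, inside).astype(float)
        bright = ((v > 125.0) & inside).astype(float)
        chans = []
        for ind in (band, bright):
            blurred = gaussian_filter(ind, sigma=self.blur_sigma)
            chans.append(block_reduce(blurred, (self.downsample, self.downsample), np.mean))
        chans.append(np.full_like(chans[0], 0.5))
        return ActivationStack(np.stack(chans), layer_name="band_oracle")

    # -- gradient --------------------------------------------------------
    def gradient(self, image: StandardizedImage, target_class: str) -> np.ndarray:
        """d P(target) / d pixel via a smooth band-membership surrogate."""
        lo, hi = _band_bounds(self.attend_band)
        center, halfwidth = (lo + hi) / 2.0, (hi - lo) / 2.0
        v = np.asarray(image.pixels, dtype=float)
        s = np.exp(-0.5 * ((v - center) / halfwidth) ** 2)
        n = float(image.plaque_mask.sum())
        f_soft = float(s[image.plaque_mask].sum() / n)
        z = self.sharpness * f_soft
        p = 1.0 / (1.0 + np.exp(-2.0 * z))
        ds_dv = s * (-(v - center) / halfwidth**2)
        grad = np.where(image.plaque_mask, p * (1 - p) * 2.0 * self.sharpness * ds_dv / n, 0.0)
        if class_index(target_class) != self._attend_idx:
            grad = -grad
        return grad


class LinearScoringModel(ScoringModel):
    """Linear test double: attended-class score is w . x (flattened image)."""

    def __init__(self, weights: np.ndarray, attend_class: str = SY):
        self.weights = np.asarray(weights, dtype=float)
        self._attend_idx = class_index(attend_class)
        self.attend_class = attend_class

    def _score(self, image: StandardizedImage) -> float:
        return float((self.weights * np.asarray(image.pixels, dtype=float)).sum())

    def predict_proba(self, image: StandardizedImage) -> np.ndarray:
        z = self._score(image)
        p = 1.0 / (1.0 + np.exp(-2.0 * z))
        probs = np.empty(2)
        probs[self._attend_idx] = p
        probs[1 - self._attend_idx] = 1.0 - p
        return probs

    def activations(self, image: StandardizedImage) -> ActivationStack:
        return ActivationStack(self.weights[None, ...], layer_name="linear")

    def gradient(self, image: StandardizedImage, target_class: str) -> np.ndarray:
        z = self._score(image)
        p = 1.0 / (1.0 + np.exp(-2.0 * z))
        grad = 2.0 * p * (1 - p) * self.weights
        if class_index(target_class) != self._attend_idx:
            grad = -grad
        return grad


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe for an externally supplied CNN head.

    Mirrors the frozen-backbone transfer-learning setup: a 128-unit ReLU
    dense layer with 0.6 dropout trained with categorical cross-entropy
    and RMSprop, initial learning rate 1e-4 stepped down by a factor of
    0.6 every 7 epochs, early stopping with patience 20, and rotation /
    flip / shear augmentation.  No trainer ships with this package; the
    config documents and validates the recipe for models plugged in via
    :class:`ScoringModel`.
    """

    dense_units: int = 128
    dropout: float = 0.6
    batch_size: int = 12
    loss: str = "categorical_crossentropy"
    optimizer: str = "rmsprop"
    initial_lr: float = 0.0001
    lr_decay_factor: float = 0.6
    lr_decay_every: int = 7
    early_stop_patience: int = 20
    rotation_range_deg: float = 20.0
    horizontal_flip: bool = True
    vertical_flip: bool = True
    shear_range_deg: float = 50.0
    seeds: tuple = (7, 12, 42)

    def __post_init__(self):
        for name in ("dropout", "lr_decay_factor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.dense_units < 1:
            raise ValueError("batch size and dense units must be positive")
        if not self.initial_lr > 0:
            raise ValueError("initial learning rate must be positive")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train / validation / test id lists."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("split partitions overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, part) for part, ids in
                (("train", self.train_ids), ("val", self.val_ids), ("test", self.test_ids))
                for i in ids]
        return pd.DataFrame(rows, columns=["sample_id", "partition"])


def stratified_split(
    manifest: pd.DataFrame,
    test_fraction: float = 0.2,
    val_fraction_of_rest: float = 11 / 95,
    seed: int = 0,
) -> DatasetSplit:
    """Per-class floor-rule split into train / validation / test.

    Per class: test count = floor(test_fraction * n); validation count =
    floor(val_fraction_of_rest * remaining); the rest trains.  Membership
    is shuffled by ``seed``.  On a balanced 236-image manifest the defaults
    yield 168 / 22 / 46 with 84 / 11 / 23 per class.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    present = set(manifest["class_label"])
    for label in CLASSES:
        if label not in present:
            raise ValueError(f"class {label} has zero members")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for label in CLASSES:
        ids = manifest.loc[manifest["class_label"] == label, "sample_id"].tolist()
        order = rng.permutation(len(ids))
        ids = [ids[i] for i in order]
        n_test = int(np.floor(test_fraction * len(ids)))
        n_val = int(np.floor(val_fraction_of_rest * (len(ids) - n_test)))
        test.extend(ids[:n_test])
        val.extend(ids[n_test : n_test + n_val])
        train.extend(ids[n_test + n_val :])
    return DatasetSplit(tuple(train), tuple(val), tuple(test))


def predict_batch(
    model: ScoringModel, images: list[StandardizedImage]
) -> tuple[np.ndarray, list[str]]:
    """Probability vectors and argmax labels; ties at 0.5 break toward ASY."""
    if not images:
        return np.empty((0, 2)), []
    probs = np.stack([model.predict_proba(im) for im in images])
    sy_idx = class_index(SY)
    labels = [SY if p[sy_idx] > 0.5 else ASY for p in probs]
    return probs, labels
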