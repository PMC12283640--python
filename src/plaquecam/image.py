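"""Raster containers shared by the whole pipeline.

Every image is an 8-bit grayscale raster (row-major, origin top-left,
0-based indices) carrying its isotropic pixel density in px/mm.  After
standardization everything lives on one fixed 512 x 224 (width x height)
grid so that heatmaps, composition contours and the plaque mask share a
single coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

#: Standardized canvas, numpy order (rows, cols) == (height, width).
CANVAS_HEIGHT = 224
CANVAS_WIDTH = 512
CANVAS_SHAPE = (CANVAS_HEIGHT, CANVAS_WIDTH)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, 0-based, half-open (x, y are the top-left corner)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError(f"rectangle must be non-empty, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise ValueError("rectangle origin must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.slices]

    def scaled(self, factor: float) -> "Rect":
        """Rectangle after isotropic rescaling of the raster by ``factor``."""
        x0 = int(round(self.x * factor))
        y0 = int(round(self.y * factor))
        x1 = max(x0 + 1, int(round((self.x + self.w) * factor)))
        y1 = max(y0 + 1, int(round((self.y + self.h) * factor)))
        return Rect(x0, y0, x1 - x0, y1 - y0)

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.y + self.h <= shape[0] and self.x + self.w <= shape[1]

    def intersects_mask(self, mask: np.ndarray) -> bool:
        return bool(mask[self.slices].any())


def _check_raster(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2D grayscale raster, got shape {pixels.shape}")
    if pixels.size == 0:
        raise ValueError("empty raster")
    if float(pixels.min()) < 0 or float(pixels.max()) > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return pixels


@dataclass
class UltrasoundImage:
    """B-mode grayscale raster plus its pixel density (px/mm, isotropic)."""

    pixels: np.ndarray
    density: float

    def __post_init__(self):
        self.pixels = _check_raster(self.pixels)
        if not self.density > 0:
            raise ValueError(f"pixel density must be positive, got {self.density}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ReferenceRegions:
    """Blood (lumen) and adventitia reference ROIs for intensity normalization."""

    blood_roi: Rect
    adventitia_roi: Rect

    def scaled(self, factor: float) -> "ReferenceRegions":
        return ReferenceRegions(self.blood_roi.scaled(factor), self.adventitia_roi.scaled(factor))


@dataclass
class StandardizedImage:
    """Image resampled onto the fixed 512 x 224 grid, with its plaque mask.

    ``provenance`` records the applied scale factors, the intensity-map
    coefficients and the post-normalization reference medians, so any
    standardized raster can be audited.
    """

    pixels: np.ndarray
    plaque_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.plaque_mask = np.asarray(self.plaque_mask).astype(bool)
        if self.pixels.shape != CANVAS_SHAPE:
            raise ValueError(
                f"standardized raster must be {CANVAS_SHAPE} (rows, cols), got {self.pixels.shape}"
            )
        if self.plaque_mask.shape != CANVAS_SHAPE:
            raise ValueError("plaque mask must share the standardized canvas shape")
        if not self.plaque_mask.any():
            raise ValueError("plaque mask is empty")


def load_grayscale(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF into a uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_grayscale(pixels: np.ndarray, path: str | Path) -> None:
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    save_grayscale(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8), path)


def load_mask(path: str | Path) -> np.ndarray:
    return load_grayscale(path) > 127
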