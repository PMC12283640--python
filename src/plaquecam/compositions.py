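"""Six-band grayscale composition contours inside the plaque.

Each plaque pixel of a standardized image is assigned to one of six
echogenicity bands that proxy tissue composition: black (GS <= 25; lipid
cores / juxtaluminal black areas), blue (25 < GS <= 50) and green
(50 < GS <= 75) for fibro-fatty tissue, yellow (75 < GS <= 100) and orange
(100 < GS <= 125) as intermediate-to-calcified, and red (GS > 125) for
calcified areas.  The bands partition [0, 255], so the per-band pixel
counts partition the plaque area exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import StandardizedImage

#: Band order everywhere in the package: index 0..5 = BK, BL, G, Y, O, R.
COMPOSITIONS = ("bk", "bl", "g", "y", "o", "r")
COMPOSITION_NAMES = ("black", "blue", "green", "yellow", "orange", "red")

#: Inclusive upper grayscale bound of each band (lower bound is exclusive).
BAND_UPPER = (25, 50, 75, 100, 125, 255)

#: Representative grayscale level of each band, used by the phantom renderer.
BAND_CENTERS = (12, 38, 63, 88, 113, 180)

#: Fixed display RGB per band for contour rendering.
DISPLAY_COLORS = (
    (0, 0, 0),        # black
    (0, 0, 255),      # blue
    (0, 255, 0),      # green
    (255, 255, 0),    # yellow
    (255, 165, 0),    # orange
    (255, 0, 0),      # red
)

_BAND_EDGES = np.array([26, 51, 76, 101, 126])  # np.digitize bins


def band_label(gs: int | np.ndarray) -> int | np.ndarray:
    """Band index (0..5) of a grayscale value; vectorized.

    GS = 25 is black, GS = 26 is blue (lower bounds exclusive, upper
    inclusive), GS > 125 is red.
    """
    return np.digitize(gs, _BAND_EDGES)


@dataclass
class CompositionMap:
    """Per-pixel composition label raster on the standardized grid.

    ``labels`` holds 0 outside the plaque and band_index + 1 (1..6) inside.
    """

    labels: np.ndarray
    plaque_mask: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.plaque_mask = np.asarray(self.plaque_mask, dtype=bool)
        if self.labels.shape != self.plaque_mask.shape:
            raise ValueError("labels and plaque mask shapes differ")
        if (self.labels[~self.plaque_mask] != 0).any():
            raise ValueError("labels must be empty (0) outside the plaque mask")
        inside = self.labels[self.plaque_mask]
        if inside.size and ((inside < 1) | (inside > 6)).any():
            raise ValueError("plaque pixels must carry a band label in 1..6")

    @property
    def gt_area(self) -> int:
        return int(self.plaque_mask.sum())

    def pixel_counts(self) -> np.ndarray:
        """6-vector of per-band pixel counts inside the plaque."""
        return np.bincount(self.labels[self.plaque_mask] - 1, minlength=6).astype(int)

    def band_mask(self, band: int) -> np.ndarray:
        """Binary raster of one band's pixels (band index 0..5)."""
        return self.labels == band + 1


@dataclass
class AreaProportions:
    """Composition areas relative to the total plaque area (percentages)."""

    pixel_counts: np.ndarray
    to_gt: np.ndarray
    gt_area: int


def segment_compositions(img: StandardizedImage) -> CompositionMap:
    """Label every plaque pixel of a standardized image by its GS band."""
    labels = np.zeros(img.pixels.shape, dtype=np.uint8)
    inside = img.plaque_mask
    labels[inside] = band_label(img.pixels[inside]) + 1
    return CompositionMap(labels, inside)


def composition_proportions(comp_map: CompositionMap) -> AreaProportions:
    """Per-band plaque-area percentages: to_gt[c] = 100 * count[c] / gt_area."""
    gt_area = comp_map.gt_area
    if gt_area == 0:
        raise ValueError("plaque area is zero")
    counts = comp_map.pixel_counts()
    return AreaProportions(counts, 100.0 * counts / gt_area, gt_area)


def render_contour_image(
    comp_map: CompositionMap, background: np.ndarray | None = None
) -> np.ndarray:
    """Paint each plaque pixel its band's display color over the grayscale background."""
    shape = comp_map.labels.shape
    if background is None:
        background = np.zeros(shape, dtype=np.uint8)
    rgb = np.repeat(np.asarray(background, dtype=np.uint8)[..., None], 3, axis=2)
    palette = np.asarray(DISPLAY_COLORS, dtype=np.uint8)
    inside = comp_map.plaque_mask
    rgb[inside] = palette[comp_map.labels[inside] - 1]
    return rgb


def labels_from_contour(rgb: np.ndarray, plaque_mask: np.ndarray) -> np.ndarray:
    """Inverse of :func:`render_contour_image` inside the plaque (exact colors)."""
    rgb = np.asarray(rgb)
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    labels = np.zeros(rgb.shape[:2], dtype=np.uint8)
    for idx, color in enumerate(DISPLAY_COLORS):
        hit = plaque_mask & np.all(rgb == np.asarray(color, dtype=np.uint8), axis=2)
        labels[hit] = idx + 1
    if (labels[plaque_mask] == 0).any():
        raise ValueError("plaque pixel with a color outside the six-band palette")
    return labels
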