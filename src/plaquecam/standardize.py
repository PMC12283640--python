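"""Image standardization: resolution, intensity, crop and resize.

Scans from different machines arrive at different pixel densities and gain
settings, so all downstream area measurements are made comparable by
(1) resampling to a common 20 px/mm density, (2) linearly rescaling
intensities so the blood (lumen) grayscale median maps to ~0 and the
adventitia median to ~190, and (3) cropping to the plaque bounding box plus
a small background margin and stretching to the fixed 512 x 224 canvas.

The intensity map is the classical two-reference-point linear scaling:

    v  ->  clamp(round((v - Mb) * (Ta - Tb) / (Ma - Mb) + Tb), 0, 255)

with Mb, Ma the blood and adventitia ROI grayscale medians and Tb, Ta the
target values (defaults 0 and 190).  Because the map is monotone and the
median is taken with the lower-median convention, the output ROI medians
land exactly on the targets.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .image import (
    CANVAS_SHAPE,
    ReferenceRegions,
    StandardizedImage,
    UltrasoundImage,
)

TARGET_DENSITY = 20.0  # px/mm
BLOOD_TARGET = 0
ADVENTITIA_TARGET = 190
DEFAULT_MARGIN_PX = 10  # 0.5 mm at 20 px/mm


def lower_median(values: np.ndarray) -> int:
    """Median with the lower-median convention for even-sized samples.

    Keeps the statistic an attained integer grayscale value, so the
    two-point map sends it exactly onto its target.
    """
    flat = np.sort(np.asarray(values), axis=None)
    if flat.size == 0:
        raise ValueError("median of an empty region")
    return int(flat[(flat.size - 1) // 2])


def _resize_pixels(pixels: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    out = resize(
        pixels.astype(float),
        out_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _resize_mask(mask: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize preserving the label dtype (bool or integer)."""
    mask = np.asarray(mask)
    out = resize(
        mask.astype(float),
        out_shape,
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return (out > 0.5) if mask.dtype == bool else np.rint(out).astype(mask.dtype)


def normalize_resolution(
    img: UltrasoundImage,
    target_density: float = TARGET_DENSITY,
    masks: tuple[np.ndarray, ...] = (),
) -> UltrasoundImage | tuple[UltrasoundImage, tuple[np.ndarray, ...]]:
    """Resample to ``target_density`` px/mm (bilinear; masks nearest-neighbor).

    Output dimensions are round(dim * target_density / density).  If the
    image is already at the target density it is returned unchanged.  When
    ``masks`` are given, returns ``(image, resampled_masks)``.
    """
    if not img.density > 0:
        raise ValueError("pixel density must be positive")
    factor = target_density / img.density
    if factor == 1.0:
        return (img, tuple(masks)) if masks else img
    h, w = img.shape
    out_shape = (max(1, int(round(h * factor))), max(1, int(round(w * factor))))
    out = UltrasoundImage(_resize_pixels(img.pixels, out_shape), target_density)
    if masks:
        return out, tuple(_resize_mask(m, out_shape) for m in masks)
    return out


def intensity_map_coefficients(
    img: UltrasoundImage,
    refs: ReferenceRegions,
    blood_target: int = BLOOD_TARGET,
    adventitia_target: int = ADVENTITIA_TARGET,
) -> tuple[int, int, float]:
    """(Mb, Ma, slope) of the two-point linear map; rejects Ma <= Mb."""
    for roi in (refs.blood_roi, refs.adventitia_roi):
        if not roi.inside(img.shape):
            raise ValueError(f"reference ROI {roi} falls outside the {img.shape} raster")
    mb = lower_median(refs.blood_roi.extract(img.pixels))
    ma = lower_median(refs.adventitia_roi.extract(img.pixels))
    if ma <= mb:
        raise ValueError(
            "degenerate reference regions: adventitia median "
            f"({ma}) must exceed blood median ({mb})"
        )
    slope = (adventitia_target - blood_target) / (ma - mb)
    return mb, ma, slope


def normalize_intensity(
    img: UltrasoundImage,
    refs: ReferenceRegions,
    blood_target: int = BLOOD_TARGET,
    adventitia_target: int = ADVENTITIA_TARGET,
) -> UltrasoundImage:
    """Two-reference-point linear intensity scaling.

    Maps the blood ROI median onto ``blood_target`` and the adventitia ROI
    median onto ``adventitia_target``; consequently the output blood median
    lies in [0, 5] and the adventitia median in [185, 190] at the defaults.
    """
    mb, _ma, slope = intensity_map_coefficients(img, refs, blood_target, adventitia_target)
    mapped = (img.pixels.astype(float) - mb) * slope + blood_target
    out = np.clip(np.rint(mapped), 0, 255).astype(np.uint8)
    return UltrasoundImage(out, img.density)


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1), half-open, of the mask's bounding box."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty plaque mask")
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def crop_and_resize(
    img: UltrasoundImage,
    plaque_mask: np.ndarray,
    margin_px: int = DEFAULT_MARGIN_PX,
    canvas: tuple[int, int] = CANVAS_SHAPE,
    extra_masks: tuple[np.ndarray, ...] = (),
) -> StandardizedImage | tuple[StandardizedImage, tuple[np.ndarray, ...]]:
    """Crop to the plaque bounding box + margin, stretch onto the canvas.

    The crop window is clipped at the raster borders.  The stretch does not
    preserve aspect ratio (plain resize, bilinear for pixels,
    nearest-neighbor for masks).  ``extra_masks`` (e.g. generator-side
    composition truth) ride along through the same geometry with
    nearest-neighbor interpolation.
    """
    if margin_px < 0:
        raise ValueError("margin must be non-negative")
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    r0, r1, c0, c1 = mask_bbox(plaque_mask)
    h, w = img.shape
    r0 = max(0, r0 - margin_px)
    c0 = max(0, c0 - margin_px)
    r1 = min(h, r1 + margin_px)
    c1 = min(w, c1 + margin_px)
    window = (slice(r0, r1), slice(c0, c1))
    crop_shape = (r1 - r0, c1 - c0)
    pixels = _resize_pixels(img.pixels[window], canvas)
    mask = _resize_mask(plaque_mask[window], canvas)
    provenance = {
        "crop_window": {"row0": r0, "row1": r1, "col0": c0, "col1": c1},
        "scale_y": canvas[0] / crop_shape[0],
        "scale_x": canvas[1] / crop_shape[1],
        "margin_px": margin_px,
    }
    std = StandardizedImage(pixels, mask, provenance)
    if extra_masks:
        resized = tuple(
            resize(
                np.asarray(m)[window].astype(float),
                canvas,
                order=0,
                mode="edge",
                anti_aliasing=False,
                preserve_range=True,
            ).astype(np.asarray(m).dtype)
            for m in extra_masks
        )
        return std, resized
    return std


def standardize_sample(
    img: UltrasoundImage,
    plaque_mask: np.ndarray,
    refs: ReferenceRegions,
    blood_target: int = BLOOD_TARGET,
    adventitia_target: int = ADVENTITIA_TARGET,
    margin_px: int = DEFAULT_MARGIN_PX,
    target_density: float = TARGET_DENSITY,
    extra_masks: tuple[np.ndarray, ...] = (),
):
    """Full standardization chain: resolution -> intensity -> crop/resize.

    Returns a :class:`StandardizedImage` (plus resampled ``extra_masks`` if
    given) whose provenance also records the post-normalization blood and
    adventitia ROI medians, so the intensity contract can be audited on
    every sample.
    """
    factor = target_density / img.density
    res = normalize_resolution(img, target_density, masks=(plaque_mask, *extra_masks))
    if isinstance(res, tuple):
        img_r, masks_r = res
    else:  # identity path without masks cannot happen here (masks always given)
        img_r, masks_r = res, (plaque_mask, *extra_masks)
    plaque_r, extras_r = masks_r[0], masks_r[1:]
    refs_r = refs.scaled(factor)
    mb, ma, slope = intensity_map_coefficients(img_r, refs_r, blood_target, adventitia_target)
    img_n = normalize_intensity(img_r, refs_r, blood_target, adventitia_target)
    blood_median_out = lower_median(refs_r.blood_roi.extract(img_n.pixels))
    adv_median_out = lower_median(refs_r.adventitia_roi.extract(img_n.pixels))
    out = crop_and_resize(img_n, plaque_r, margin_px=margin_px, extra_masks=extras_r)
    if isinstance(out, tuple):
        std, extras_out = out
    else:
        std, extras_out = out, ()
    std.provenance.update(
        {
            "resolution_factor": factor,
            "blood_median_in": mb,
            "adventitia_median_in": ma,
            "intensity_slope": slope,
            "intensity_intercept": blood_target - mb * slope,
            "blood_median_out": blood_median_out,
            "adventitia_median_out": adv_median_out,
        }
    )
    if extra_masks:
        return std, extras_out
    return std
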