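"""Speckled carotid-plaque phantoms with known composition ground truth.

A phantom emulates the geometry a longitudinal B-mode carotid scan hands to
the pipeline: a dark lumen band at the top, a bright adventitia band at the
bottom, and an elliptical plaque in between whose interior is tiled by
flood-grown blobs, one per grayscale composition band, with known label
masks.  Class-conditional composition mixtures reproduce the qualitative
cohort pattern: dark (GS <= 25) areas are the largest band in both classes
and even larger in symptomatic plaques, while asymptomatic plaques mix
echolucent and echogenic areas.  Per-image acquisition jitter (pixel
density, multiplicative gain, additive offset) makes standardization
non-trivial, and multiplicative gamma speckle plus a 1 px Gaussian blur
provide a standard B-mode texture proxy.

Everything is reproducible: identical (parameters, seed) yield identical
rasters and byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .compositions import BAND_CENTERS
from .image import Rect, ReferenceRegions, UltrasoundImage, load_grayscale, load_mask, save_grayscale, save_mask
from .labels import ASY, CLASSES, SY

# Fixed phantom layout (pre-standardization pixels).
LUMEN_HEIGHT = 26
ADVENTITIA_HEIGHT = 26
PLAQUE_GAP = 8       # rows between lumen/adventitia bands and the plaque
SIDE_PAD = 24        # columns flanking the plaque

LUMEN_BASE = 2       # near-anechoic blood
TISSUE_BASE = 58     # unremarkable wall/background echo
ADVENTITIA_BASE = 208


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults of the phantom study conditions.

    ``class_means`` are the per-class mean composition fractions
    (BK, BL, G, Y, O, R) of the Dirichlet draw; the symptomatic class puts
    more mass on the black band.  ``pixel_density`` is sampled per image
    from a truncated normal echoing the 14.29 +/- 3.07 px/mm spread of
    mixed-machine acquisitions; plaque axes are sampled in mm so their
    pixel extent co-varies with density.
    """

    class_means: dict = field(
        default_factory=lambda: {
            ASY: (0.30, 0.18, 0.14, 0.11, 0.09, 0.18),
            SY: (0.50, 0.20, 0.12, 0.08, 0.05, 0.05),
        }
    )
    concentration: float = 60.0
    density_mean: float = 14.3      # px/mm
    density_sd: float = 3.0
    density_range: tuple = (8.0, 22.0)
    major_mm: tuple = (13.85, 4.85, 6.0, 20.0)   # mean, sd, lo, hi
    minor_mm: tuple = (4.8, 1.6, 2.5, 7.5)
    jba_probability: dict = field(default_factory=lambda: {ASY: 0.3, SY: 0.7})
    # Offsets shift the black level upward only: a downward shift is censored
    # by display clipping at 0 and destroys the blood reference, which the
    # two-point linear normalization (like any linear method) cannot invert.
    gain_range: tuple = (0.75, 1.25)
    offset_range: tuple = (0.0, 25.0)
    speckle_strength: float = 0.35

    def validate(self) -> None:
        for label in CLASSES:
            means = np.asarray(self.class_means[label], dtype=float)
            if means.shape != (6,):
                raise ValueError(f"class means for {label} must be a 6-vector")
            if abs(means.sum() - 1.0) > 1e-9:
                raise ValueError(f"class means for {label} must sum to 1, got {means.sum()}")
            if (means <= 0).any():
                raise ValueError("class means must be strictly positive")
        if not self.concentration > 0:
            raise ValueError("Dirichlet concentration must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """One phantom's full generative description (deterministic to render)."""

    class_label: str
    canvas_size_px: tuple       # (height, width)
    pixel_density: float        # px/mm, pre-standardization
    plaque_axes_px: tuple       # (major, minor) full axis lengths
    composition_fractions: np.ndarray
    jba_adjacent_to_lumen: bool
    gain_offset: tuple          # (multiplicative gain, additive offset)
    speckle_strength: float
    rng_seed: int

    def __post_init__(self):
        object.__setattr__(
            self, "composition_fractions", np.asarray(self.composition_fractions, dtype=float)
        )
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if abs(self.composition_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if not self.pixel_density > 0:
            raise ValueError("pixel density must be positive")
        if self.speckle_strength < 0:
            raise ValueError("speckle strength must be non-negative")
        h, w = self.canvas_size_px
        major, minor = self.plaque_axes_px
        if major > w - 2 or minor > h - LUMEN_HEIGHT - ADVENTITIA_HEIGHT - 2:
            raise ValueError("plaque does not fit inside the canvas")


@dataclass
class PhantomSample:
    """Rendered phantom: raster, plaque mask, label truth and reference ROIs."""

    image: UltrasoundImage
    plaque_mask: np.ndarray
    composition_truth: np.ndarray   # 0 outside plaque, band index + 1 inside
    blood_roi: Rect
    adventitia_roi: Rect
    class_label: str
    spec: PhantomSpec | None = None
    sample_id: str | None = None

    def __post_init__(self):
        self.plaque_mask = np.asarray(self.plaque_mask, dtype=bool)
        self.composition_truth = np.asarray(self.composition_truth)
        if (self.composition_truth[~self.plaque_mask] != 0).any():
            raise ValueError("composition truth must be zero outside the plaque mask")
        for roi in (self.blood_roi, self.adventitia_roi):
            if roi.intersects_mask(self.plaque_mask):
                raise ValueError("reference ROI intersects the plaque")

    @property
    def refs(self) -> ReferenceRegions:
        return ReferenceRegions(self.blood_roi, self.adventitia_roi)


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def sample_phantom_spec(
    class_label: str,
    params: GeneratorConfig | None = None,
    rng_seed: int = 0,
) -> PhantomSpec:
    """Draw one phantom spec for a class; deterministic in (label, params, seed).

    Composition fractions are a Dirichlet sample with alpha =
    concentration * class_mean; an infinite concentration degenerates to
    the class mean exactly.
    """
    params = params or GeneratorConfig()
    params.validate()
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    if rng_seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(rng_seed)
    means = np.asarray(params.class_means[class_label], dtype=float)
    if np.isinf(params.concentration):
        fractions = means.copy()
    else:
        fractions = rng.dirichlet(means * params.concentration)
    density = _truncated_normal(rng, params.density_mean, params.density_sd, *params.density_range)
    major_mm = _truncated_normal(rng, *params.major_mm)
    minor_mm = _truncated_normal(rng, *params.minor_mm)
    major_px = max(24, int(round(major_mm * density)))
    minor_px = max(12, int(round(minor_mm * density)))
    jba = bool(rng.random() < params.jba_probability[class_label])
    gain = float(rng.uniform(*params.gain_range))
    offset = float(rng.uniform(*params.offset_range))
    canvas = (
        LUMEN_HEIGHT + PLAQUE_GAP + minor_px + PLAQUE_GAP + ADVENTITIA_HEIGHT,
        major_px + 2 * SIDE_PAD,
    )
    return PhantomSpec(
        class_label=class_label,
        canvas_size_px=canvas,
        pixel_density=density,
        plaque_axes_px=(major_px, minor_px),
        composition_fractions=fractions,
        jba_adjacent_to_lumen=jba,
        gain_offset=(gain, offset),
        speckle_strength=params.speckle_strength,
        rng_seed=int(rng_seed),
    )


def _grow_blobs(
    coords: np.ndarray,
    seeds: np.ndarray,
    targets: np.ndarray,
    max_iter: int = 100,
    tol: float = 0.01,
) -> np.ndarray:
    """Assign plaque pixels to compositions as quota-matched convex blobs.

    Additively-weighted (power-diagram) nearest-seed assignment: each pixel
    goes to argmin_k(||p - s_k||^2 - w_k), and the per-seed weights w_k are
    iterated until each cell's pixel share matches its target fraction.
    Power cells are convex, so every composition forms one connected blob.
    """
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2).astype(float)
    n, k = d2.shape
    w = np.zeros(k)
    spread = d2.mean()
    best_assign, best_err = np.argmin(d2, axis=1), np.inf
    for _ in range(max_iter):
        assign = np.argmin(d2 - w[None, :], axis=1)
        shares = np.bincount(assign, minlength=k) / n
        err = shares - targets
        worst = float(np.abs(err).max())
        if worst < best_err:  # keep the best iterate; the update can overshoot
            best_assign, best_err = assign, worst
        if worst < tol:
            break
        w -= 0.5 * err * spread
    return best_assign


def render_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a spec into a speckled raster with ground-truth label masks.

    Layout top-to-bottom: lumen band, plaque ellipse, adventitia band.  The
    plaque interior is tiled by one blob per composition, drawn at the
    center grayscale of its band, in proportions matching the spec within
    discretization error; when ``jba_adjacent_to_lumen`` the black blob is
    anchored at the plaque's lumen-side boundary.  Multiplicative gamma
    speckle (unit mean), a 1 px Gaussian blur, then gain/offset jitter are
    applied; ``composition_truth`` records the pre-noise labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 2]))
    h, w = spec.canvas_size_px
    major, minor = spec.plaque_axes_px
    a, b = major / 2.0, minor / 2.0
    cy = LUMEN_HEIGHT + PLAQUE_GAP + minor / 2.0
    cx = w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    plaque = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    n_plaque = int(plaque.sum())
    if n_plaque < 24:
        raise ValueError("canvas too small: plaque has almost no interior")

    quotas = np.rint(spec.composition_fractions * n_plaque).astype(int)
    active = np.flatnonzero(quotas >= 1)
    if active.size == 0:
        raise ValueError("composition fractions incompatible with the plaque size")
    targets = spec.composition_fractions[active]
    targets = targets / targets.sum()

    coords = np.column_stack(np.nonzero(plaque)).astype(float)  # (row, col)
    seeds = np.empty((active.size, 2))
    min_sep = 0.4 * b  # near-coincident seeds destabilize the quota iteration
    for i, comp in enumerate(active):
        if comp == 0 and spec.jba_adjacent_to_lumen:
            seeds[i] = (cy - b + 1.0, cx)  # black blob touches the lumen side
        else:
            for attempt in range(200):
                ry = rng.uniform(cy - b, cy + b)
                rx = rng.uniform(cx - a, cx + a)
                inside = ((rx - cx) / a) ** 2 + ((ry - cy) / b) ** 2 <= 0.85
                sep = min_sep if attempt < 100 else 0.0
                far = all(np.hypot(ry - s0, rx - s1) > sep for s0, s1 in seeds[:i])
                if inside and far:
                    seeds[i] = (ry, rx)
                    break
            else:
                raise ValueError("canvas too small to place composition seeds")
    if active.size == 1:
        assign = np.zeros(n_plaque, dtype=int)
    else:
        assign = _grow_blobs(coords, seeds, targets)

    truth = np.zeros((h, w), dtype=np.uint8)
    truth[plaque] = (active[assign] + 1).astype(np.uint8)

    base = np.full((h, w), float(TISSUE_BASE))
    base[:LUMEN_HEIGHT] = LUMEN_BASE
    base[h - ADVENTITIA_HEIGHT :] = ADVENTITIA_BASE
    centers = np.asarray(BAND_CENTERS, dtype=float)
    base[plaque] = centers[active[assign]]

    s = spec.speckle_strength
    img = base
    if s > 0:
        shape = 1.0 / (s * s)
        img = base * rng.gamma(shape, 1.0 / shape, size=base.shape)
    img = gaussian_filter(img, sigma=1.0)
    gain, offset = spec.gain_offset
    img = np.clip(np.rint(img * gain + offset), 0, 255).astype(np.uint8)

    roi_w = w // 3
    roi_x = (w - roi_w) // 2
    blood = Rect(roi_x, 3, roi_w, LUMEN_HEIGHT - 6)
    adventitia = Rect(roi_x, h - ADVENTITIA_HEIGHT + 3, roi_w, ADVENTITIA_HEIGHT - 6)
    return PhantomSample(
        image=UltrasoundImage(img, spec.pixel_density),
        plaque_mask=plaque,
        composition_truth=truth,
        blood_roi=blood,
        adventitia_roi=adventitia,
        class_label=spec.class_label,
        spec=spec,
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def generate_samples(
    n_per_class: int,
    params: GeneratorConfig | None = None,
    seed: int = 0,
) -> list[PhantomSample]:
    """Render a balanced in-memory set of 2 * n_per_class phantoms."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = params or GeneratorConfig()
    seeds = _child_seeds(seed, 2 * n_per_class)
    samples = []
    for i in range(n_per_class):
        for j, label in enumerate(CLASSES):
            spec = sample_phantom_spec(label, params, int(seeds[2 * i + j]))
            sample = render_phantom(spec)
            sample.sample_id = f"{label.lower()}_{i:04d}"
            samples.append(sample)
    return samples


_MANIFEST_COLUMNS = [
    "sample_id", "class_label", "rng_seed", "pixel_density",
    "image", "plaque_mask", "composition_truth",
    "blood_x", "blood_y", "blood_w", "blood_h",
    "adv_x", "adv_y", "adv_w", "adv_h",
]


def generate_dataset(
    n_per_class: int,
    params: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> pd.DataFrame:
    """Write a balanced phantom dataset (PNG rasters + one manifest CSV).

    Fully reproducible: the same (params, seed) produce byte-identical
    files.  Returns the manifest table; the CSV lands in
    ``out_dir/manifest.csv`` with file paths relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in generate_samples(n_per_class, params, seed):
        sid = sample.sample_id
        image_p = f"{sid}_image.png"
        mask_p = f"{sid}_plaque.png"
        truth_p = f"{sid}_truth.png"
        save_grayscale(sample.image.pixels, out_dir / image_p)
        save_mask(sample.plaque_mask, out_dir / mask_p)
        save_grayscale(sample.composition_truth, out_dir / truth_p)
        b, adv = sample.blood_roi, sample.adventitia_roi
        rows.append(
            [
                sid, sample.class_label, sample.spec.rng_seed, sample.spec.pixel_density,
                image_p, mask_p, truth_p,
                b.x, b.y, b.w, b.h, adv.x, adv.y, adv.w, adv.h,
            ]
        )
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    if manifest["sample_id"].duplicated().any():
        raise RuntimeError("duplicate sample ids in manifest")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_sample(row: pd.Series, base_dir: str | Path) -> PhantomSample:
    """Rehydrate one manifest row into a :class:`PhantomSample` (no spec)."""
    base = Path(base_dir)
    return PhantomSample(
        image=UltrasoundImage(load_grayscale(base / row["image"]), float(row["pixel_density"])),
        plaque_mask=load_mask(base / row["plaque_mask"]),
        composition_truth=load_grayscale(base / row["composition_truth"]),
        blood_roi=Rect(int(row["blood_x"]), int(row["blood_y"]), int(row["blood_w"]), int(row["blood_h"])),
        adventitia_roi=Rect(int(row["adv_x"]), int(row["adv_y"]), int(row["adv_w"]), int(row["adv_h"])),
        class_label=row["class_label"],
        sample_id=row["sample_id"],
    )
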