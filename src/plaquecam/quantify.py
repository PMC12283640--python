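"""Uniform-heatmap coverage and the four overlap-proportion families.

The CAM is reduced to a flat coverage region over the plaque (all strictly
positive heatmap values, no value threshold), and per plaque four families
of percentages are measured against the six-band composition map:

  a. GTplq-Heatmap   -- plaque area covered by the heatmap, % of plaque;
  b. BktoGT..RtoGT   -- each composition's area, % of plaque area;
  c. HMPinBk..HMPinR -- covered part of each composition, % of that
                        composition's own area (0 when the composition is
                        absent, with a presence flag);
  d. HMPBk..HMPR     -- covered part of each composition, % of the total
                        coverage area (sums to 100 over the six bands).

The exact identity hmp_of * gtplq_heatmap = hmp_in * to_gt (as fractions)
holds per composition and is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cam import Heatmap
from .compositions import COMPOSITIONS, CompositionMap


class DegenerateCoverageError(ValueError):
    """Raised when an empty (degenerate) coverage mask is measured."""


@dataclass
class CoverageMask:
    """Binary uniform-heatmap support restricted to the plaque."""

    mask: np.ndarray
    tau: float
    degenerate: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.degenerate != (not self.mask.any()):
            raise ValueError("degenerate flag must mirror an empty mask")


@dataclass
class OverlapMeasurements:
    """One plaque's four measurement families (percentages)."""

    gtplq_heatmap: float
    to_gt: np.ndarray
    hmp_in: np.ndarray
    hmp_of: np.ndarray
    present: np.ndarray          # which compositions have nonzero area
    sample_id: str | None = None
    class_label: str | None = None
    predicted_label: str | None = None

    def as_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "class": self.class_label,
            "predicted": self.predicted_label,
            "gtplq_heatmap": self.gtplq_heatmap,
        }
        for i, c in enumerate(COMPOSITIONS):
            row[f"{c}_to_gt"] = float(self.to_gt[i])
        for i, c in enumerate(COMPOSITIONS):
            row[f"hmp_in_{c}"] = float(self.hmp_in[i])
        for i, c in enumerate(COMPOSITIONS):
            row[f"hmp_{c}"] = float(self.hmp_of[i])
        for i, c in enumerate(COMPOSITIONS):
            row[f"present_{c}"] = bool(self.present[i])
        row["degenerate"] = False
        return row


def heatmap_support(hm: Heatmap, plaque_mask: np.ndarray, tau: float = 0.0) -> CoverageMask:
    """Coverage = plaque pixels with heatmap value strictly above ``tau``.

    The default tau = 0 keeps every strictly positive heatmap value (the
    parameter-free "all heatmap values" convention) while excluding exact
    zeros.  An empty result is flagged degenerate; such samples carry no
    measurements and are excluded (and counted) downstream.
    """
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    if hm.values.shape != plaque_mask.shape:
        raise ValueError(
            f"grid mismatch: heatmap {hm.values.shape} vs plaque mask {plaque_mask.shape}"
        )
    mask = plaque_mask & (hm.values > tau)
    return CoverageMask(mask, tau, degenerate=not mask.any())


def measure_overlap(
    coverage: CoverageMask,
    comp_map: CompositionMap,
    sample_id: str | None = None,
    class_label: str | None = None,
    predicted_label: str | None = None,
) -> OverlapMeasurements:
    """Compute the four proportion families for one plaque.

    Raises :class:`DegenerateCoverageError` on degenerate coverage (the
    flag propagates; no measurements are fabricated).
    """
    if coverage.degenerate:
        raise DegenerateCoverageError("degenerate coverage: no measurements for this sample")
    if coverage.mask.shape != comp_map.labels.shape:
        raise ValueError("coverage and composition map grids differ")
    if (coverage.mask & ~comp_map.plaque_mask).any():
        raise ValueError("coverage extends outside the composition map's plaque")

    gt_area = comp_map.gt_area
    cov_area = int(coverage.mask.sum())
    counts = comp_map.pixel_counts().astype(float)
    inter = np.bincount(
        comp_map.labels[coverage.mask] - 1, minlength=6
    ).astype(float)

    present = counts > 0
    to_gt = 100.0 * counts / gt_area
    hmp_in = np.where(present, 100.0 * inter / np.where(present, counts, 1), 0.0)
    hmp_of = 100.0 * inter / cov_area
    return OverlapMeasurements(
        gtplq_heatmap=100.0 * cov_area / gt_area,
        to_gt=to_gt,
        hmp_in=hmp_in,
        hmp_of=hmp_of,
        present=present,
        sample_id=sample_id,
        class_label=class_label,
        predicted_label=predicted_label,
    )


def degenerate_row(sample_id: str, class_label: str, predicted_label: str | None) -> dict:
    """Measurements-CSV row for a sample whose heatmap had no support."""
    row = {"sample_id": sample_id, "class": class_label, "predicted": predicted_label,
           "gtplq_heatmap": np.nan}
    for prefix in ("{}_to_gt", "hmp_in_{}", "hmp_{}"):
        for c in COMPOSITIONS:
            row[prefix.format(c)] = np.nan
    for c in COMPOSITIONS:
        row[f"present_{c}"] = False
    row["degenerate"] = True
    return row


def measurements_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Stack per-sample measurement rows into the measurements table."""
    columns = (
        ["sample_id", "class", "predicted", "gtplq_heatmap"]
        + [f"{c}_to_gt" for c in COMPOSITIONS]
        + [f"hmp_in_{c}" for c in COMPOSITIONS]
        + [f"hmp_{c}" for c in COMPOSITIONS]
        + [f"present_{c}" for c in COMPOSITIONS]
        + ["degenerate"]
    )
    return pd.DataFrame(rows, columns=columns)
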