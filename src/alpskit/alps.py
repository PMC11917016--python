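"""Spherical-ROI ALPS index computation.

Four 5 mm spheres per subject — projection and association fibers on each
side of the lateral ventricle — yield the ratio
``(meanX_proj + meanX_assoc) / (meanY_proj + meanZ_assoc)`` per hemisphere,
and the combined index is the mean of the two sides.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRoiWarning, SpecificationError, UndefinedIndexError
from .geometry import Volume3D, roi_mean, sphere_mask
from .tensor import DiffusivityMaps

__all__ = ["RoiSpec", "AlpsResult", "alps_index", "combine_sides", "compute_alps"]

SIDES = ("right", "left")
FIBERS = ("projection", "association")


@dataclass(frozen=True)
class RoiSpec:
    """One spherical ROI, positioned in world mm (DTI space)."""

    side: str
    fiber: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 5.0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise SpecificationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.fiber not in FIBERS:
            raise SpecificationError(f"fiber must be one of {FIBERS}, got {self.fiber!r}")
        if not (self.radius_mm > 0):
            raise SpecificationError("radius_mm must be positive")


def full_roi_set(rois: list[RoiSpec]) -> dict:
    """Index a list of four ROIs by (side, fiber), enforcing completeness."""
    table: dict[tuple[str, str], RoiSpec] = {}
    for roi in rois:
        key = (roi.side, roi.fiber)
        if key in table:
            raise SpecificationError(f"duplicate ROI for {key}")
        table[key] = roi
    missing = {(s, f) for s in SIDES for f in FIBERS} - set(table)
    if missing:
        raise SpecificationError(f"missing ROI(s): {sorted(missing)}")
    return table


@dataclass
class AlpsResult:
    """Per-subject ROI means (mm^2/s) and ALPS indices."""

    means: dict = field(default_factory=dict)  # side -> {x_proj, x_assoc, y_proj, z_assoc}
    alps_r: float = float("nan")
    alps_l: float = float("nan")
    alps_comb: float = float("nan")
    roi_voxel_counts: dict = field(default_factory=dict)  # "side:fiber" -> int
    subject_id: str | None = None

    def to_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id}
        for side in SIDES:
            m = self.means.get(side, {})
            for key in ("x_proj", "x_assoc", "y_proj", "z_assoc"):
                row[f"{key}_{side[0]}"] = m.get(key, float("nan"))
        for k, v in self.roi_voxel_counts.items():
            row[f"n_{k.replace(':', '_')}"] = v
        row.update(alps_r=self.alps_r, alps_l=self.alps_l, alps_comb=self.alps_comb)
        return row


def alps_index(x_proj: float, x_assoc: float, y_proj: float, z_assoc: float) -> float:
    """The ALPS ratio (x_proj + x_assoc) / (y_proj + z_assoc)."""
    den = y_proj + z_assoc
    if not den > 0:
        raise UndefinedIndexError(f"non-positive denominator {den}")
    return (x_proj + x_assoc) / den


def combine_sides(alps_r: float, alps_l: float) -> float:
    """Combined index = mean of hemispheric indices; NaN if either is missing."""
    if math.isnan(alps_r) or math.isnan(alps_l):
        return float("nan")
    return (alps_r + alps_l) / 2.0


def compute_alps(maps: DiffusivityMaps, rois: list[RoiSpec]) -> AlpsResult:
    """Extract the four sphere means per side and form the indices.

    A side whose spheres miss the grid entirely yields NaN for that side (and
    for the combined index) rather than an exception.
    """
    table = full_roi_set(rois)
    result = AlpsResult(subject_id=next((r.subject_id for r in rois if r.subject_id), None))
    shape, affine = maps.dxx.shape, maps.affine
    per_side: dict[str, float] = {}
    for side in SIDES:
        masks = {}
        for fiber in FIBERS:
            roi = table[(side, fiber)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyRoiWarning)
                m = sphere_mask(shape, affine, roi.center_mm, roi.radius_mm)
            masks[fiber] = m & maps.mask
            result.roi_voxel_counts[f"{side}:{fiber}"] = int(masks[fiber].sum())
        means = {
            "x_proj": roi_mean(maps.dxx.data, masks["projection"]),
            "x_assoc": roi_mean(maps.dxx.data, masks["association"]),
            "y_proj": roi_mean(maps.dyy.data, masks["projection"]),
            "z_assoc": roi_mean(maps.dzz.data, masks["association"]),
        }
        result.means[side] = means
        if any(math.isnan(v) for v in means.values()):
            per_side[side] = float("nan")
        else:
            per_side[side] = alps_index(**means)
    result.alps_r = per_side["right"]
    result.alps_l = per_side["left"]
    result.alps_comb = combine_sides(result.alps_r, result.alps_l)
    return result
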