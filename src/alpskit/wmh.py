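"""WMH quantification inside and outside the ALPS ROI spheres.

Lesion-probability maps (FLAIR space) are thresholded, ROI centers are
mapped from DTI to FLAIR world coordinates, 5 mm spheres are rebuilt around
the transformed centers in FLAIR geometry, and intersecting lesion voxels
are counted.  A subject with any lesion voxel in any sphere is flagged for
exclusion; lesion load outside the spheres is summarized as volume and a
26-connected component count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .alps import RoiSpec, full_roi_set, SIDES, FIBERS
from .errors import DataValidationError, EmptyRoiWarning, GeometryError
from .geometry import Volume3D, sphere_mask, voxel_volume_mm3

__all__ = [
    "LesionMap",
    "SpaceTransform",
    "WmhRoiReport",
    "binarize_lesions",
    "map_roi_to_flair",
    "wmh_in_roi",
    "partition_cohort",
]


@dataclass
class LesionMap:
    """Thresholded lesion-probability map in FLAIR space."""

    probability: Volume3D
    threshold: float
    binary: np.ndarray

    @property
    def affine(self) -> np.ndarray:
        return self.probability.affine


def binarize_lesions(prob: Volume3D, threshold: float = 0.5) -> LesionMap:
    """Inclusive thresholding of a probability volume (values must be in [0,1])."""
    data = prob.data
    if np.nanmin(data) < 0 or np.nanmax(data) > 1:
        raise DataValidationError("lesion probabilities must lie in [0, 1]")
    if not (0 <= threshold <= 1):
        raise DataValidationError("threshold must lie in [0, 1]")
    return LesionMap(prob, float(threshold), data >= threshold)


@dataclass
class SpaceTransform:
    """World-to-world (mm) map from DTI space into FLAIR space."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise GeometryError("transform must be a 4x4 matrix")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise GeometryError("transform is singular")

    @classmethod
    def identity(cls) -> "SpaceTransform":
        return cls(np.eye(4))

    def apply(self, points_mm) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.asarray(points_mm).ndim == 1 else out

    def inverse(self) -> "SpaceTransform":
        return SpaceTransform(np.linalg.inv(self.matrix))


def map_roi_to_flair(center_mm_dti, transform: SpaceTransform) -> np.ndarray:
    """Transform one ROI center from DTI world mm into FLAIR world mm."""
    return transform.apply(np.asarray(center_mm_dti, dtype=float))


@dataclass
class WmhRoiReport:
    """Lesion load inside each ROI sphere and in the rest of the brain."""

    subject_id: str | None
    roi_counts: dict  # "side:fiber" -> lesion voxel count
    roi_volumes_mm3: dict  # "side:fiber" -> mm^3
    wmh_r: float  # total lesion volume (mm^3) in right-side spheres
    wmh_l: float
    wmh_comb: float
    excluded: bool
    inside_volume_mm3: float  # union of spheres (robust to overlapping spheres)
    outside_volume_mm3: float
    total_volume_mm3: float
    global_wmh_count: int  # 26-connected components outside the spheres

    def to_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id}
        for k, v in self.roi_counts.items():
            row[f"count_{k.replace(':', '_')}"] = v
        row.update(
            wmh_r=self.wmh_r,
            wmh_l=self.wmh_l,
            wmh_comb=self.wmh_comb,
            excluded=self.excluded,
            outside_volume_mm3=self.outside_volume_mm3,
            total_volume_mm3=self.total_volume_mm3,
            global_wmh_count=self.global_wmh_count,
        )
        return row


def wmh_in_roi(
    lesions: LesionMap,
    rois: list[RoiSpec],
    transform: SpaceTransform | None = None,
    subject_id: str | None = None,
) -> WmhRoiReport:
    """Count lesion voxels intersecting each transformed 5 mm sphere.

    Spheres are constructed with the ROI's mm radius in FLAIR world space
    around the transformed center; volumes use the FLAIR voxel volume.
    """
    transform = transform or SpaceTransform.identity()
    table = full_roi_set(rois)
    binary = lesions.binary
    shape = binary.shape
    affine = lesions.affine
    voxvol = voxel_volume_mm3(affine)

    counts: dict[str, int] = {}
    volumes: dict[str, float] = {}
    union = np.zeros(shape, dtype=bool)
    for side in SIDES:
        for fiber in FIBERS:
            roi = table[(side, fiber)]
            center_flair = map_roi_to_flair(roi.center_mm, transform)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyRoiWarning)
                sphere = sphere_mask(shape, affine, center_flair, roi.radius_mm)
            if not sphere.any():
                warnings.warn(
                    f"ROI {side}:{fiber} has empty intersection with the FLAIR grid",
                    EmptyRoiWarning,
                )
            n = int(np.count_nonzero(binary & sphere))
            counts[f"{side}:{fiber}"] = n
            volumes[f"{side}:{fiber}"] = n * voxvol
            union |= sphere

    wmh_r = sum(v for k, v in volumes.items() if k.startswith("right"))
    wmh_l = sum(v for k, v in volumes.items() if k.startswith("left"))
    total = float(np.count_nonzero(binary)) * voxvol
    inside = float(np.count_nonzero(binary & union)) * voxvol
    outside_mask = binary & ~union
    outside = float(np.count_nonzero(outside_mask)) * voxvol
    n_comp = int(ndimage.label(outside_mask, structure=np.ones((3, 3, 3)))[1])

    return WmhRoiReport(
        subject_id=subject_id,
        roi_counts=counts,
        roi_volumes_mm3=volumes,
        wmh_r=wmh_r,
        wmh_l=wmh_l,
        wmh_comb=wmh_r + wmh_l,
        excluded=any(c > 0 for c in counts.values()),
        inside_volume_mm3=inside,
        outside_volume_mm3=outside,
        total_volume_mm3=total,
        global_wmh_count=n_comp,
    )


def partition_cohort(reports: list[WmhRoiReport]) -> tuple[list, list]:
    """Split per-subject reports into (clean, contaminated) on the excluded flag."""
    clean = [r for r in reports if not r.excluded]
    contaminated = [r for r in reports if r.excluded]
    return clean, contaminated
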