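"""Volumes, affines and spherical ROI masks.

All world coordinates are millimetres in a RAS frame: +x right, +y anterior,
+z superior.  Voxel-to-world maps are full 4x4 affines; distances are always
computed in world space so anisotropic voxels are handled correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import polar

from .errors import EmptyRoiWarning, GeometryError

__all__ = [
    "Volume3D",
    "rotation_part",
    "sphere_mask",
    "roi_mean",
    "voxel_volume_mm3",
]


@dataclass
class Volume3D:
    """A 3-D scalar grid with a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3-D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-15:
            raise GeometryError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel spacing (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def rotation_part(affine: np.ndarray) -> np.ndarray:
    """Orthogonal rotation factor of the affine's linear part (polar decomposition)."""
    lin = np.asarray(affine, dtype=float)[:3, :3]
    if abs(np.linalg.det(lin)) < 1e-15:
        raise GeometryError("affine is singular")
    rot, _ = polar(lin)
    return rot


def voxel_volume_mm3(affine: np.ndarray) -> float:
    return float(abs(np.linalg.det(np.asarray(affine, dtype=float)[:3, :3])))


def sphere_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    center_mm,
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose world-space centers lie within ``radius_mm``
    (inclusive) of ``center_mm``.

    An empty intersection raises :class:`EmptyRoiWarning` (a warning, not an
    error) and returns the all-false mask.
    """
    center = np.asarray(center_mm, dtype=float)
    if not np.all(np.isfinite(center)):
        raise GeometryError("sphere center must be finite")
    if not (radius_mm > 0):
        raise GeometryError("sphere radius must be positive")
    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)

    # Bounding box: map the world-space AABB corners of the sphere to voxel space.
    corners = center + radius_mm * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    vox = corners @ inv[:3, :3].T + inv[:3, 3]
    lo = np.maximum(np.floor(vox.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + 2, np.asarray(shape))

    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        warnings.warn("sphere lies entirely outside the grid", EmptyRoiWarning)
        return mask

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    d2 = np.sum((world - center) ** 2, axis=-1)
    # Inclusive boundary; tolerance absorbs affine round-off at the shell.
    inside = d2 <= radius_mm**2 + 1e-9
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    if not mask.any():
        warnings.warn("sphere contains no voxel centers", EmptyRoiWarning)
    return mask


def roi_mean(data: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``data`` over ``mask``; NaN for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    return float(np.asarray(data)[mask].mean())
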