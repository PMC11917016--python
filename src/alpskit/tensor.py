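"""Diffusion tensor fitting and axis-diffusivity / FA map derivation.

The fit is the standard unweighted log-linear least squares of
``ln S = ln S0 - b g'Dg`` solved per voxel.  Tensor components are stored in
the voxel frame in lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz);
:func:`diffusivity_maps` rotates them into the world RAS frame before taking
diagonals, so the x/y/z maps always refer to anatomical axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError, InsufficientDesignError
from .geometry import Volume3D, rotation_part

__all__ = ["DWISet", "TensorField", "DiffusivityMaps", "fit_tensor", "diffusivity_maps"]

# lower-triangular component order used throughout (and on disk)
LT_ORDER = ("dxx", "dxy", "dyy", "dxz", "dyz", "dzz")
_LT_INDEX = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclass
class DWISet:
    """A 4-D diffusion-weighted acquisition with its gradient table."""

    signals: np.ndarray  # (nx, ny, nz, nvol)
    bvals: np.ndarray  # (nvol,) s/mm^2
    bvecs: np.ndarray  # (nvol, 3), unit norm for weighted volumes
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signals.ndim != 4:
            raise DataValidationError("signals must be 4-D (x, y, z, volume)")
        nvol = self.signals.shape[3]
        if len(self.bvals) != nvol or len(self.bvecs) != nvol:
            raise DataValidationError("bvals/bvecs length must match volume count")
        validate_design(self.bvals, self.bvecs)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def validate_design(bvals: np.ndarray, bvecs: np.ndarray) -> None:
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float).reshape(-1, 3)
    weighted = bvals > 0
    if np.count_nonzero(~weighted) < 1:
        raise InsufficientDesignError("at least one b=0 volume is required")
    if np.count_nonzero(weighted) < 6:
        raise InsufficientDesignError("at least 6 diffusion-weighted directions required")
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise DataValidationError("weighted b-vectors must be unit norm (tol 1e-6)")
    if np.linalg.matrix_rank(_design_matrix(bvals, bvecs)[:, 1:]) < 6:
        raise InsufficientDesignError("gradient directions are collinear (rank-deficient design)")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors (mm^2/s) in the voxel frame.

    ``components`` has shape (nx, ny, nz, 6) in ``LT_ORDER``; ``mask`` marks
    voxels where the tensor is trustworthy (positive signals everywhere).
    """

    components: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.components.ndim != 4 or self.components.shape[3] != 6:
            raise DataValidationError("tensor components must have shape (x, y, z, 6)")
        if self.mask is None:
            self.mask = np.ones(self.components.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]  # type: ignore[return-value]

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric 3x3 matrices, shape (..., 3, 3)."""
        out = np.zeros(self.shape + (3, 3))
        for c, (i, j) in zip(range(6), _LT_INDEX):
            out[..., i, j] = self.components[..., c]
            out[..., j, i] = self.components[..., c]
        return out

    @classmethod
    def from_matrices(cls, mats: np.ndarray, affine: np.ndarray, mask=None) -> "TensorField":
        mats = np.asarray(mats, dtype=float)
        comp = np.stack([mats[..., i, j] for (i, j) in _LT_INDEX], axis=-1)
        return cls(comp, affine, mask)


@dataclass
class DiffusivityMaps:
    """Axis diffusivity maps plus FA and color-FA, all in the world RAS frame."""

    dxx: Volume3D
    dyy: Volume3D
    dzz: Volume3D
    fa: Volume3D
    color_fa: np.ndarray  # (nx, ny, nz, 3), channels = FA * |e1| (R=x, G=y, B=z)
    mask: np.ndarray

    @property
    def affine(self) -> np.ndarray:
        return self.dxx.affine


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows: [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    b = np.asarray(bvals, dtype=float)[:, None]
    g = np.asarray(bvecs, dtype=float)
    x, y, z = g[:, 0:1], g[:, 1:2], g[:, 2:3]
    return np.hstack(
        [np.ones_like(b), -b * x * x, -b * y * y, -b * z * z,
         -2 * b * x * y, -2 * b * x * z, -2 * b * y * z]
    )


def fit_tensor(dwi: DWISet) -> TensorField:
    """Log-linear least-squares tensor fit.

    Voxels with any non-positive signal are marked invalid and get a zero
    tensor; everything else is solved in one vectorized ``lstsq``.
    """
    X = _design_matrix(dwi.bvals, dwi.bvecs)
    sig = dwi.signals
    valid = np.all(sig > 0, axis=-1)
    comp = np.zeros(sig.shape[:3] + (6,))
    if valid.any():
        logs = np.log(sig[valid])  # (nvox, nvol)
        beta, *_ = np.linalg.lstsq(X, logs.T, rcond=None)  # (7, nvox)
        # beta rows 1..6 are Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
        dxx, dyy, dzz, dxy, dxz, dyz = beta[1:7]
        comp[valid] = np.stack([dxx, dxy, dyy, dxz, dyz, dzz], axis=-1)
    return TensorField(comp, dwi.affine, valid)


def _fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    lam = np.clip(evals, 1e-12, None)  # clamp only for FA, never for diagonals
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num / den)
    return np.nan_to_num(fa, nan=0.0)


def diffusivity_maps(tensors: TensorField) -> DiffusivityMaps:
    """Rotate tensors into the world frame and derive dxx/dyy/dzz, FA, color FA.

    The diagonal maps use the raw rotated tensor (no eigenvalue clamping), as
    the ALPS ratio averages diagonals; FA/color-FA clamp negative eigenvalues
    at 1e-12.
    """
    R = rotation_part(tensors.affine)
    D = tensors.as_matrices()
    Dw = np.einsum("ab,...bc,dc->...ad", R, D, R)

    evals, evecs = np.linalg.eigh(Dw)
    fa = _fa_from_eigenvalues(evals)
    fa = np.where(tensors.mask, fa, 0.0)
    e1 = evecs[..., :, -1]  # principal eigenvector, world frame
    color = fa[..., None] * np.abs(e1)

    aff = tensors.affine

    def vol(x: np.ndarray) -> Volume3D:
        return Volume3D(np.ascontiguousarray(x), aff)

    return DiffusivityMaps(
        dxx=vol(Dw[..., 0, 0]),
        dyy=vol(Dw[..., 1, 1]),
        dzz=vol(Dw[..., 2, 2]),
        fa=vol(fa),
        color_fa=color,
        mask=tensors.mask.copy(),
    )
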