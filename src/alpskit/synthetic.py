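"""Synthetic DTI/FLAIR phantoms and cohorts with known ground truth.

The phantom places, per hemisphere, a projection-fiber slab (principal
diffusion along z) and an association-fiber slab (principal diffusion along
y) lateral to a central ventricle block, on an axis-aligned RAS grid.  A
single multiplier ``glymph_x`` scales the x-axis diffusivity of both fiber
populations, so the ground-truth ALPS ratio of the phantom equals
``glymph_x`` exactly when the two perpendicular eigenvalues agree.

Cohort generation draws per-subject true indices from group-specific normal
distributions and produces covariates, CDR/MMSE scores and CSF amyloid
ratios that satisfy the AD/HC classification predicate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError, InvalidConfigError, PlacementError
from .geometry import Volume3D
from .tensor import DWISet, TensorField, validate_design

__all__ = [
    "Box",
    "RegionLayout",
    "PhantomConfig",
    "PhantomTruth",
    "LesionSpec",
    "CohortConfig",
    "generate_phantom",
    "phantom_flair",
    "simulate_dwi",
    "inject_wmh",
    "generate_cohort",
    "default_gradient_table",
]

SIDES = ("right", "left")
FIBERS = ("projection", "association")


@dataclass(frozen=True)
class Box:
    """Half-open voxel-index box [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]

    def center_index(self) -> np.ndarray:
        return (np.asarray(self.lo) + np.asarray(self.hi) - 1) / 2.0

    def overlaps(self, other: "Box") -> bool:
        return all(l1 < h2 and l2 < h1 for l1, h1, l2, h2 in zip(self.lo, self.hi, other.lo, other.hi))


@dataclass
class RegionLayout:
    """Voxel-index placement of the fiber slabs and the ventricle block."""

    fiber_boxes: dict  # (side, fiber) -> Box
    ventricle: Box | None = None

    def validate(self, grid_shape) -> None:
        keys = set(self.fiber_boxes)
        expected = {(s, f) for s in SIDES for f in FIBERS}
        if keys != expected:
            raise InvalidConfigError(f"layout must define exactly {sorted(expected)}")
        boxes = list(self.fiber_boxes.values())
        for b in boxes + ([self.ventricle] if self.ventricle else []):
            if any(l < 0 or h > n or l >= h for l, h, n in zip(b.lo, b.hi, grid_shape)):
                raise InvalidConfigError(f"box {b} outside grid {grid_shape}")
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if boxes[i].overlaps(boxes[j]):
                    raise InvalidConfigError("projection/association regions overlap")


def default_layout(grid_shape) -> RegionLayout:
    """Fractional default layout: fiber slabs lateral to a midline ventricle."""
    n = np.asarray(grid_shape)

    def box(fx0, fx1, fy0, fy1, fz0, fz1) -> Box:
        lo = (int(round(fx0 * n[0])), int(round(fy0 * n[1])), int(round(fz0 * n[2])))
        hi = (int(round(fx1 * n[0])), int(round(fy1 * n[1])), int(round(fz1 * n[2])))
        return Box(lo, hi)

    fiber = {}
    for side, (fx0, fx1) in (("left", (0.08, 0.36)), ("right", (0.64, 0.92))):
        fiber[(side, "projection")] = box(fx0, fx1, 0.28, 0.48, 0.2, 0.8)
        fiber[(side, "association")] = box(fx0, fx1, 0.52, 0.72, 0.2, 0.8)
    return RegionLayout(fiber_boxes=fiber, ventricle=box(0.42, 0.58, 0.3, 0.7, 0.3, 0.7))


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    region_layout: RegionLayout | None = None
    base_eigenvalues: tuple[float, float] = (1.4e-3, 0.6e-3)  # (parallel, perpendicular) mm^2/s
    glymph_x: float | Mapping[str, float] = 1.35
    background_md: float = 0.7e-3
    ventricle_md: float = 3.0e-3
    s0: float = 1000.0
    rician_sigma: float = 0.0
    seed: int = 0

    def glymph_for(self, side: str) -> float:
        if isinstance(self.glymph_x, Mapping):
            return float(self.glymph_x[side])
        return float(self.glymph_x)

    @property
    def layout(self) -> RegionLayout:
        return self.region_layout if self.region_layout is not None else default_layout(self.grid_shape)

    def validate(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise InvalidConfigError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidConfigError("voxel sizes must be positive")
        if any(ev <= 0 for ev in self.base_eigenvalues):
            raise InvalidConfigError("eigenvalues must be positive")
        for side in SIDES:
            if self.glymph_for(side) <= 0:
                raise InvalidConfigError("glymph_x must be positive")
        if self.background_md <= 0 or self.ventricle_md <= 0:
            raise InvalidConfigError("region diffusivities must be positive")
        self.layout.validate(self.grid_shape)

    def affine(self) -> np.ndarray:
        """Axis-aligned RAS affine with the grid centered on the world origin."""
        aff = np.eye(4)
        vs = np.asarray(self.voxel_size_mm, dtype=float)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * vs
        return aff


@dataclass
class PhantomTruth:
    """Ground-truth record emitted alongside every phantom."""

    diffusivities: dict  # side -> {x_proj, x_assoc, y_proj, z_assoc}
    true_alps: dict  # side -> float
    roi_centers_mm: dict  # "side:fiber" -> (x, y, z)
    roi_radius_mm: float = 5.0
    lesions: list = field(default_factory=list)

    @property
    def true_alps_comb(self) -> float:
        return (self.true_alps["right"] + self.true_alps["left"]) / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_alps_comb"] = self.true_alps_comb
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        d = dict(d)
        d.pop("true_alps_comb", None)
        return cls(**d)


def generate_phantom(config: PhantomConfig) -> tuple[TensorField, PhantomTruth]:
    """Build the tensor field and its consistent ground-truth record."""
    config.validate()
    par, perp = config.base_eigenvalues
    aff = config.affine()
    shape = tuple(int(n) for n in config.grid_shape)

    comp = np.zeros(shape + (6,))
    # background / ventricle isotropic
    comp[..., 0] = comp[..., 2] = comp[..., 5] = config.background_md
    layout = config.layout
    if layout.ventricle is not None:
        sl = layout.ventricle.slices()
        for c in (0, 2, 5):
            comp[sl + (c,)] = config.ventricle_md

    diff: dict[str, dict[str, float]] = {}
    alps: dict[str, float] = {}
    centers: dict[str, list[float]] = {}
    vs = np.asarray(config.voxel_size_mm)
    origin = aff[:3, 3]
    for side in SIDES:
        gx = config.glymph_for(side)
        for fiber in FIBERS:
            box = layout.fiber_boxes[(side, fiber)]
            sl = box.slices()
            if fiber == "projection":  # principal along z
                dxx, dyy, dzz = gx * perp, perp, par
            else:  # association: principal along y
                dxx, dyy, dzz = gx * perp, par, perp
            comp[sl + (0,)] = dxx
            comp[sl + (2,)] = dyy
            comp[sl + (5,)] = dzz
            centers[f"{side}:{fiber}"] = list(box.center_index() * vs + origin)
        x_val = gx * perp
        diff[side] = {"x_proj": x_val, "x_assoc": x_val, "y_proj": perp, "z_assoc": perp}
        alps[side] = (diff[side]["x_proj"] + diff[side]["x_assoc"]) / (
            diff[side]["y_proj"] + diff[side]["z_assoc"]
        )

    tf = TensorField(comp, aff)
    truth = PhantomTruth(diffusivities=diff, true_alps=alps, roi_centers_mm=centers)
    return tf, truth


def phantom_flair(config: PhantomConfig, voxel_size_mm=None) -> Volume3D:
    """Synthetic FLAIR-like volume covering the phantom's world extent.

    White matter ~100, ventricle CSF dark (~30).  ``voxel_size_mm`` may differ
    from the DTI grid to exercise cross-space ROI transforms.
    """
    if voxel_size_mm is None:
        data = np.full(config.grid_shape, 100.0)
        if config.layout.ventricle is not None:
            data[config.layout.ventricle.slices()] = 30.0
        return Volume3D(data, config.affine())

    vs = np.asarray(voxel_size_mm, dtype=float)
    extent = np.asarray(config.grid_shape) * np.asarray(config.voxel_size_mm)
    shape = np.maximum(np.ceil(extent / vs).astype(int), 1)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -(shape - 1) / 2.0 * vs
    vol = Volume3D(np.full(tuple(shape), 100.0), aff)
    if config.layout.ventricle is not None:
        # carve the ventricle by world-coordinate membership
        box = config.layout.ventricle
        daff = config.affine()
        lo_w = np.asarray(box.lo) @ daff[:3, :3].T + daff[:3, 3]
        hi_w = (np.asarray(box.hi) - 1) @ daff[:3, :3].T + daff[:3, 3]
        idx = np.indices(tuple(shape)).reshape(3, -1).T
        world = idx @ aff[:3, :3].T + aff[:3, 3]
        inside = np.all((world >= lo_w) & (world <= hi_w), axis=1)
        vol.data.reshape(-1)[inside] = 30.0
    return vol


def default_gradient_table(bval: float = 1000.0, n_b0: int = 1):
    """A fixed 12-direction scheme (icosahedral vertices) plus b=0 volumes."""
    phi = (1 + np.sqrt(5)) / 2
    raw = np.array(
        [[0, 1, phi], [0, 1, -phi], [0, -1, phi], [1, phi, 0], [1, -phi, 0], [-1, phi, 0],
         [phi, 0, 1], [phi, 0, -1], [-phi, 0, 1], [1, 1, 1], [1, -1, 1], [-1, 1, 1]],
        dtype=float,
    )
    dirs = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(len(dirs), float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def simulate_dwi(
    tensors: TensorField,
    bvals,
    bvecs,
    s0: float = 1000.0,
    rician_sigma: float = 0.0,
    seed: int = 0,
) -> DWISet:
    """Forward-simulate DWI signals ``s0 * exp(-b g'Dg)`` with Rician noise.

    Noise model: magnitude of (signal + N(0, sigma)) + i N(0, sigma), one
    freshly seeded generator per call.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float).reshape(-1, 3)
    validate_design(bvals, bvecs)
    if rician_sigma < 0:
        raise InvalidConfigError("rician_sigma must be non-negative")

    D = tensors.as_matrices()
    quad = np.einsum("vi,...ij,vj->...v", bvecs, D, bvecs)  # g'Dg per voxel/volume
    signal = s0 * np.exp(-bvals * quad)
    if rician_sigma > 0:
        rng = np.random.default_rng(seed)
        re = signal + rng.normal(0.0, rician_sigma, signal.shape)
        im = rng.normal(0.0, rician_sigma, signal.shape)
        signal = np.hypot(re, im)
    return DWISet(signal, bvals, bvecs, tensors.affine)


@dataclass
class LesionSpec:
    """An ellipsoidal WMH lesion, specified in world mm."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    lesion_md: float = 1.2e-3
    flair_intensity: float = 2.0
    probability: float = 1.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise DataValidationError("lesion semi-axes must be positive")
        if not (0.0 <= self.probability <= 1.0):
            raise DataValidationError("lesion probability must lie in [0, 1]")
        if self.lesion_md <= 0:
            raise DataValidationError("lesion_md must be positive")


def _ellipsoid_mask(shape, affine, lesion: LesionSpec) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    u = (world - np.asarray(lesion.center_mm)) / np.asarray(lesion.semi_axes_mm)
    return (np.sum(u * u, axis=1) <= 1.0 + 1e-12).reshape(shape)


def inject_wmh(
    tensors: TensorField,
    flair: Volume3D,
    prob_map: Volume3D,
    lesions: list[LesionSpec],
) -> tuple[TensorField, Volume3D, Volume3D, int]:
    """Insert ellipsoidal lesions into tensor field, FLAIR and probability map.

    Inside each ellipsoid the tensor becomes isotropic ``lesion_md * I``, the
    FLAIR intensity is multiplied, and the probability map is max-combined.
    Inputs are not mutated; the count of modified DTI voxels is returned.
    """
    comp = tensors.components.copy()
    fl = Volume3D(flair.data.copy(), flair.affine.copy())
    pm = Volume3D(prob_map.data.copy(), prob_map.affine.copy())

    # placement check against the DTI grid's voxel bounds
    inv = np.linalg.inv(tensors.affine)
    n_modified = 0
    for les in lesions:
        c_vox = np.asarray(les.center_mm) @ inv[:3, :3].T + inv[:3, 3]
        if np.any(c_vox < -0.5) or np.any(c_vox > np.asarray(tensors.shape) - 0.5):
            raise PlacementError(f"lesion center {les.center_mm} outside the DTI grid")

        m = _ellipsoid_mask(tensors.shape, tensors.affine, les)
        comp[m] = [les.lesion_md, 0.0, les.lesion_md, 0.0, 0.0, les.lesion_md]
        n_modified += int(m.sum())

        mf = _ellipsoid_mask(fl.shape, fl.affine, les)
        fl.data[mf] *= les.flair_intensity
        mp = _ellipsoid_mask(pm.shape, pm.affine, les)
        pm.data[mp] = np.maximum(pm.data[mp], les.probability)

    out = TensorField(comp, tensors.affine.copy(), tensors.mask.copy())
    return out, fl, pm, n_modified


@dataclass
class CohortConfig:
    """Parameters for a two-group synthetic cohort.

    Default index means/SDs follow the most widely separated cohort reported
    for this design (AD 1.217 +/- 0.122, HC 1.356 +/- 0.139); amyloid values
    are in arbitrary calibrated units and only their association direction
    with the true index is meaningful.
    """

    n_ad: int = 16
    n_hc: int = 18
    alps_mean_ad: float = 1.217
    alps_sd_ad: float = 0.122
    alps_mean_hc: float = 1.356
    alps_sd_hc: float = 0.139
    age_mean_ad: float = 75.0
    age_sd_ad: float = 6.0
    age_mean_hc: float = 72.0
    age_sd_hc: float = 5.0
    p_female: float = 0.5
    edu_mean: float = 14.0
    edu_sd: float = 3.0
    abeta_cutoff: float = 0.05
    abeta_slope: float = 0.05  # ratio units per index unit; positive by default
    abeta_noise_sd: float = 0.004
    abeta40_mean: float = 10.0
    abeta40_sd: float = 1.0
    hemisphere_asym_sd: float = 0.04
    cohort_label: str = "SYNTH"
    seed: int = 0

    def validate(self) -> None:
        if self.n_ad < 2 or self.n_hc < 2:
            raise InvalidConfigError("need at least 2 subjects per group")
        for sd in (self.alps_sd_ad, self.alps_sd_hc, self.age_sd_ad, self.age_sd_hc):
            if sd <= 0:
                raise InvalidConfigError("distribution SDs must be positive")
        if not (0 < self.abeta_cutoff):
            raise InvalidConfigError("abeta_cutoff must be positive")


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a subject table whose rows satisfy the AD/HC classification rule.

    AD rows get CDR >= 0.5 and an amyloid ratio at or below the cutoff; HC
    rows get CDR = 0 and a ratio above it.  The ratio carries the configured
    slope on the subject's true index within each group (clipping to the
    legal side of the cutoff guarantees the classification predicate).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    cut = config.abeta_cutoff
    for group, n in (("AD", config.n_ad), ("HC", config.n_hc)):
        ad = group == "AD"
        mean = config.alps_mean_ad if ad else config.alps_mean_hc
        sd = config.alps_sd_ad if ad else config.alps_sd_hc
        alps = rng.normal(mean, sd, n)
        asym = rng.normal(0.0, config.hemisphere_asym_sd, n)
        age = rng.normal(config.age_mean_ad if ad else config.age_mean_hc,
                         config.age_sd_ad if ad else config.age_sd_hc, n)
        sex = (rng.random(n) < config.p_female).astype(int)
        edu = np.clip(np.round(rng.normal(config.edu_mean, config.edu_sd, n)), 8, 22)
        if ad:
            cdr = rng.choice([0.5, 1.0, 2.0], size=n, p=[0.7, 0.25, 0.05])
            mmse = np.clip(np.round(rng.normal(22, 3, n)), 5, 30)
            base = 0.6 * cut
        else:
            cdr = np.zeros(n)
            mmse = np.clip(np.round(rng.normal(29, 1, n)), 24, 30)
            base = 1.5 * cut
        ratio = base + config.abeta_slope * (alps - mean) + rng.normal(0, config.abeta_noise_sd, n)
        ratio = np.clip(ratio, 0.1 * cut, cut) if ad else np.clip(ratio, np.nextafter(cut, np.inf), 3 * cut)
        ab40 = np.clip(rng.normal(config.abeta40_mean, config.abeta40_sd, n), 1e-3, None)
        for i in range(n):
            rows.append(
                dict(
                    subject_id=f"{config.cohort_label}-{group}-{i:04d}",
                    cohort=config.cohort_label,
                    group=group,
                    age=float(age[i]),
                    sex=int(sex[i]),
                    education=float(edu[i]),
                    cdr_global=float(cdr[i]),
                    mmse=float(mmse[i]),
                    abeta40=float(ab40[i]),
                    abeta42=float(ratio[i] * ab40[i]),
                    abeta_ratio=float(ratio[i]),
                    alps_true=float(alps[i]),
                    alps_r_true=float(alps[i] + asym[i]),
                    alps_l_true=float(alps[i] - asym[i]),
                )
            )
    return pd.DataFrame(rows)
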