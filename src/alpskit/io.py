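"""File I/O: NIfTI volumes, FSL bval/bvec tables, ROI JSON, transforms, tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .alps import RoiSpec
from .errors import DataValidationError
from .geometry import Volume3D
from .tensor import DWISet, TensorField
from .wmh import SpaceTransform

__all__ = [
    "save_volume",
    "load_volume",
    "save_tensor_field",
    "load_tensor_field",
    "save_dwi",
    "load_dwi",
    "save_bvals_bvecs",
    "load_bvals_bvecs",
    "save_rois",
    "load_rois",
    "load_transform",
    "save_json",
    "load_json",
    "sha256_file",
]


def save_volume(vol: Volume3D, path) -> Path:
    path = Path(path)
    nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine).to_filename(str(path))
    return path


def load_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise DataValidationError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return Volume3D(data, img.affine)


def save_tensor_field(tf: TensorField, path) -> Path:
    """Store as a 4-D volume of 6 lower-triangular components."""
    path = Path(path)
    nib.Nifti1Image(np.asarray(tf.components, dtype=np.float64), tf.affine).to_filename(str(path))
    return path


def load_tensor_field(path) -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != 6:
        raise DataValidationError(f"{path}: expected (x,y,z,6) tensor components")
    return TensorField(data, img.affine)


def save_bvals_bvecs(bvals, bvecs, bvals_path, bvecs_path) -> None:
    """FSL convention: bvals one row; bvecs three rows (x, y, z)."""
    np.savetxt(bvals_path, np.atleast_2d(np.asarray(bvals, float)), fmt="%.6g")
    np.savetxt(bvecs_path, np.asarray(bvecs, float).reshape(-1, 3).T, fmt="%.10g")


def load_bvals_bvecs(bvals_path, bvecs_path):
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise DataValidationError(f"{bvecs_path}: cannot interpret shape {bvecs.shape} as (n, 3)")
    return bvals, bvecs


def save_dwi(dwi: DWISet, nii_path, bvals_path, bvecs_path) -> None:
    nib.Nifti1Image(np.asarray(dwi.signals, dtype=np.float64), dwi.affine).to_filename(str(nii_path))
    save_bvals_bvecs(dwi.bvals, dwi.bvecs, bvals_path, bvecs_path)


def load_dwi(nii_path, bvals_path, bvecs_path) -> DWISet:
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DataValidationError(f"{nii_path}: expected 4-D DWI data")
    bvals, bvecs = load_bvals_bvecs(bvals_path, bvecs_path)
    return DWISet(data, bvals, bvecs, img.affine)


def save_rois(rois: list[RoiSpec], path) -> Path:
    path = Path(path)
    payload = [
        {
            "subject_id": r.subject_id,
            "side": r.side,
            "fiber": r.fiber,
            "center_mm": list(map(float, r.center_mm)),
            "radius_mm": r.radius_mm,
        }
        for r in rois
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_rois(path) -> list[RoiSpec]:
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise DataValidationError(f"{path}: ROI JSON must be a list of objects")
    rois = []
    for e in entries:
        try:
            rois.append(
                RoiSpec(
                    side=e["side"],
                    fiber=e["fiber"],
                    center_mm=tuple(e["center_mm"]),
                    radius_mm=float(e.get("radius_mm", 5.0)),
                    subject_id=e.get("subject_id"),
                )
            )
        except KeyError as exc:
            raise DataValidationError(f"{path}: ROI entry missing key {exc}") from exc
    return rois


def load_transform(path_or_identity) -> SpaceTransform:
    """Read a 4x4 world-mm transform from a text file; 'identity' is accepted."""
    if str(path_or_identity) == "identity":
        return SpaceTransform.identity()
    mat = np.loadtxt(path_or_identity)
    if mat.shape != (4, 4):
        raise DataValidationError(f"{path_or_identity}: expected a 4x4 matrix")
    return SpaceTransform(mat)


def save_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_table(df: pd.DataFrame, path) -> Path:
    """Deterministic table output (tab-separated for .tsv, else comma)."""
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep)
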