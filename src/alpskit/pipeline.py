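"""End-to-end orchestration: simulate or ingest, measure, filter, analyze.

One config drives the full chain: (synthetic phantom | files) -> tensor fit
-> diffusivity maps -> ALPS -> WMH-in-ROI -> clean/contaminated partition ->
group statistics.  Every random draw is derived from the run seed, so a
(config, seed) pair reproduces its outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alps import RoiSpec, compute_alps
from .errors import DataValidationError, InsufficientDesignError, InvalidConfigError
from .geometry import Volume3D
from .io import (
    load_dwi,
    load_rois,
    load_tensor_field,
    load_transform,
    load_volume,
    read_table,
    save_json,
    sha256_file,
    write_table,
)
from .stats import ancova_group, classify_subjects, linreg_standardized, log_transform_wmh, mann_whitney_u
from .synthetic import (
    CohortConfig,
    LesionSpec,
    PhantomConfig,
    default_gradient_table,
    generate_cohort,
    generate_phantom,
    inject_wmh,
    phantom_flair,
    simulate_dwi,
)
from .tensor import diffusivity_maps, fit_tensor
from .wmh import SpaceTransform, binarize_lesions, wmh_in_roi

log = logging.getLogger("alpskit.pipeline")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "truth_rois"]


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    out_dir: str = "alpskit_run"
    seed: int = 0
    lesion_threshold: float = 0.5
    abeta_cutoff: float = 0.05
    synthetic: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    analyses: list = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise InvalidConfigError(f"mode must be synthetic|files, got {self.mode!r}")
        if self.mode == "files":
            for key in ("rois", "subject_table", "subjects"):
                if key not in self.files:
                    raise InvalidConfigError(f"file mode requires files.{key}")
            for key in ("rois", "subject_table"):
                if not Path(self.files[key]).exists():
                    raise InvalidConfigError(f"missing input file: {self.files[key]}")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    counts: dict
    checksums: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def truth_rois(truth, subject_id: str | None = None) -> list[RoiSpec]:
    """ROI specs from a phantom truth manifest."""
    rois = []
    for key, center in truth.roi_centers_mm.items():
        side, fiber = key.split(":")
        rois.append(
            RoiSpec(side=side, fiber=fiber, center_mm=tuple(center),
                    radius_mm=truth.roi_radius_mm, subject_id=subject_id)
        )
    return rois


def _subject_seed(seed: int, index: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, salt, index]).generate_state(1)[0])


def _measure_subject(pcfg: PhantomConfig, lesions, threshold, sub_seed):
    """Phantom -> (lesioned) tensors -> maps -> ALPS + WMH report."""
    tf, truth = generate_phantom(pcfg)
    flair = phantom_flair(pcfg)
    prob = Volume3D(np.zeros(tf.shape), tf.affine.copy())
    if lesions:
        tf, flair, prob, _ = inject_wmh(tf, flair, prob, lesions)
    if pcfg.rician_sigma > 0:
        bvals, bvecs = default_gradient_table()
        dwi = simulate_dwi(tf, bvals, bvecs, pcfg.s0, pcfg.rician_sigma, sub_seed)
        tf_meas = fit_tensor(dwi)
    else:
        tf_meas = tf  # noise-free: the field itself is the exact fit
    maps = diffusivity_maps(tf_meas)
    rois = truth_rois(truth)
    alps = compute_alps(maps, rois)
    lesmap = binarize_lesions(prob, threshold)
    report = wmh_in_roi(lesmap, rois, SpaceTransform.identity())
    return alps, report


def _synthetic_table(config: RunConfig) -> pd.DataFrame:
    syn = config.synthetic
    cc = CohortConfig(**syn.get("cohort", {}))
    cohort = generate_cohort(cc, seed=config.seed)

    pkw = dict(syn.get("phantom", {}))
    if "grid_shape" in pkw:
        pkw["grid_shape"] = tuple(pkw["grid_shape"])
    if "voxel_size_mm" in pkw:
        pkw["voxel_size_mm"] = tuple(pkw["voxel_size_mm"])
    base = PhantomConfig(**{"grid_shape": (32, 32, 32), **pkw})

    n = len(cohort)
    n_cont = int(syn.get("n_contaminated", 0))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    contaminated_idx = set(rng.choice(n, size=min(n_cont, n), replace=False).tolist())

    rows = []
    for i, rec in cohort.iterrows():
        pcfg = replace(
            base,
            glymph_x={"right": rec.alps_r_true, "left": rec.alps_l_true},
            seed=_subject_seed(config.seed, i),
        )
        lesions = []
        if i in contaminated_idx:
            _, truth = generate_phantom(pcfg)
            key = list(truth.roi_centers_mm)[int(rng.integers(4))]
            radius = float(rng.uniform(3.0, 4.5))
            lesions = [
                LesionSpec(
                    center_mm=tuple(truth.roi_centers_mm[key]),
                    semi_axes_mm=(radius, radius, radius),
                    lesion_md=float(np.mean(pcfg.base_eigenvalues)),
                )
            ]
        alps, report = _measure_subject(pcfg, lesions, config.lesion_threshold,
                                        _subject_seed(config.seed, i, salt=1))
        row = rec.to_dict()
        row.update(alps_r=alps.alps_r, alps_l=alps.alps_l, alps_comb=alps.alps_comb)
        row.update(
            wmh_r=report.wmh_r, wmh_l=report.wmh_l, wmh_comb=report.wmh_comb,
            wmh_outside=report.outside_volume_mm3, wmh_count=report.global_wmh_count,
            excluded=report.excluded,
        )
        rows.append(row)
        if report.excluded:
            log.info("subject %s excluded: WMH in ROI (%.1f mm3)", rec.subject_id, report.wmh_comb)
    return pd.DataFrame(rows)


def _files_table(config: RunConfig) -> pd.DataFrame:
    files = config.files
    table = read_table(files["subject_table"])
    all_rois = load_rois(files["rois"])
    transform = load_transform(files.get("transform", "identity"))

    rows = []
    for entry in files["subjects"]:
        sid = entry["id"]
        rois = [r for r in all_rois if r.subject_id == sid] or [r for r in all_rois if r.subject_id is None]
        try:
            if "tensors" in entry:
                tf = load_tensor_field(entry["tensors"])
            else:
                tf = fit_tensor(load_dwi(entry["dwi"], entry["bvals"], entry["bvecs"]))
            maps = diffusivity_maps(tf)
            alps = compute_alps(maps, rois)
            row = {"subject_id": sid, "alps_r": alps.alps_r, "alps_l": alps.alps_l,
                   "alps_comb": alps.alps_comb}
            if "lesions" in entry:
                lesmap = binarize_lesions(load_volume(entry["lesions"]), config.lesion_threshold)
                rep = wmh_in_roi(lesmap, rois, transform, subject_id=sid)
                row.update(wmh_r=rep.wmh_r, wmh_l=rep.wmh_l, wmh_comb=rep.wmh_comb,
                           wmh_outside=rep.outside_volume_mm3, wmh_count=rep.global_wmh_count,
                           excluded=rep.excluded)
            else:
                row.update(wmh_r=0.0, wmh_l=0.0, wmh_comb=0.0, wmh_outside=0.0,
                           wmh_count=0, excluded=False)
            rows.append(row)
        except Exception as exc:
            log.error("stage failure for subject %s: %s", sid, exc)
            raise
    measured = pd.DataFrame(rows)
    return table.merge(measured, on="subject_id", how="inner")


def _default_analyses() -> list:
    return [
        {"kind": "ancova", "outcome": "alps_comb", "covariates": ["age", "sex"], "subset": "clean"},
        {"kind": "regression", "outcome": "alps_comb", "predictor": "abeta_ratio",
         "covariates": ["age", "sex", "education"], "subset": "clean"},
        {"kind": "regression", "outcome": "alps_comb", "predictor": "log_wmh_comb",
         "covariates": [], "subset": "contaminated"},
        {"kind": "mannwhitney", "outcome": "alps_comb", "split": "cdr0",
         "variable": "cdr_global", "subset": "clean"},
    ]


def _run_analyses(table: pd.DataFrame, analyses: list) -> list:
    out = []
    clean = table[~table["excluded"]]
    contaminated = table[table["excluded"]]
    subsets = {"clean": clean, "contaminated": contaminated, "all": table}
    for spec in analyses:
        sub = subsets[spec.get("subset", "clean")].copy()
        sub["log_wmh_comb"] = log_transform_wmh(sub["wmh_comb"]) if "wmh_comb" in sub else 0.0
        entry = {"spec": spec, "n": int(len(sub))}
        if spec["kind"] not in ("ancova", "regression", "mannwhitney"):
            raise InvalidConfigError(f"unknown analysis kind {spec['kind']!r}")
        if len(sub) == 0:
            entry["error"] = "empty subset"
            out.append(entry)
            continue
        try:
            if spec["kind"] == "ancova":
                res = ancova_group(sub, spec["outcome"], tuple(spec.get("covariates", ())))
                entry["result"] = dataclasses.asdict(res)
            elif spec["kind"] == "regression":
                res = linreg_standardized(sub, spec["outcome"], spec["predictor"],
                                          tuple(spec.get("covariates", ())))
                entry["result"] = dataclasses.asdict(res)
            elif spec["kind"] == "mannwhitney":
                from .stats import dichotomize

                labels = dichotomize(sub, spec["variable"], spec["split"])
                hi = sub.loc[labels == "high", spec["outcome"]].dropna()
                lo = sub.loc[labels == "low", spec["outcome"]].dropna()
                u, p = mann_whitney_u(hi, lo)
                entry["result"] = {"U": u, "p": p, "n_high": int(len(hi)), "n_low": int(len(lo))}
        except (InsufficientDesignError, DataValidationError) as exc:
            # a subset too small for a model is recorded, not fatal
            entry["error"] = str(exc)
        out.append(entry)
    return out


def run_pipeline(config: RunConfig) -> RunManifest:
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        table = _synthetic_table(config)
    else:
        table = _files_table(config)

    labels = classify_subjects(table, config.abeta_cutoff) if "cdr_global" in table else None
    if labels is not None:
        table["group"] = labels
    n_total = len(table)
    n_classified = int(labels.notna().sum()) if labels is not None else n_total
    n_unclassified = n_total - n_classified

    classified = table[table["group"].notna()] if "group" in table else table
    analyzed = classified[~classified["excluded"]]
    excluded = classified[classified["excluded"]]
    counts = {
        "total": n_total,
        "classified": n_classified,
        "unclassified_dropped": n_unclassified,
        "excluded_for_wmh": int(len(excluded)),
        "analyzed": int(len(analyzed)),
    }
    log.info("filter counts: %s", counts)

    analyses = config.analyses or _default_analyses()
    stats = _run_analyses(classified, analyses)

    outputs = {
        "subjects.tsv": write_table(table, out_dir / "subjects.tsv"),
        "analyzed.tsv": write_table(analyzed, out_dir / "analyzed.tsv"),
        "excluded.tsv": write_table(excluded, out_dir / "excluded.tsv"),
        "stats.json": save_json(stats, out_dir / "stats.json"),
    }
    checksums = {name: sha256_file(path) for name, path in outputs.items()}
    manifest = RunManifest(
        version=__version__,
        config_hash=config.hash(),
        seed=config.seed,
        counts=counts,
        checksums=checksums,
    )
    save_json(manifest.to_dict(), out_dir / "manifest.json")
    return manifest
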