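# alpskit

A tested, reusable pipeline for the DTI-ALPS perivascular diffusivity index:
diffusivity-map derivation from diffusion MRI, spherical-ROI ALPS index
computation, white-matter-hyperintensity (WMH) contamination bookkeeping with
an any-lesion exclusion rule, and the cohort statistics that link the index to
diagnosis, amyloid status, WMH load and cognition. A first-class synthetic
data module generates DTI/FLAIR phantoms and two-group cohorts with known
ground truth, so every stage is verifiable offline.

## Modules

| module | what it does |
| --- | --- |
| `alpskit.synthetic` | phantoms (fiber slabs + ventricle, tunable x-diffusivity), Rician DWI simulation, ellipsoidal WMH injection, cohort tables |
| `alpskit.tensor` | log-linear diffusion tensor fit, world-frame dxx/dyy/dzz, FA and color-FA maps |
| `alpskit.alps` | 5 mm spherical ROIs, per-hemisphere ALPS ratio, combined index |
| `alpskit.wmh` | lesion-probability thresholding, DTI→FLAIR ROI transforms, WMH-in-sphere counting, exclusion flag, outside-ROI load |
| `alpskit.stats` | AD/HC classification, ANCOVA + Cohen's d, standardized-β regression, Mann-Whitney U, WMH log-transform, clinical dichotomies |
| `alpskit.pipeline` | one-config orchestration of the whole chain with a reproducibility manifest |

## CLI

```bash
alpskit simulate phantom --config phantom.yaml --out sim/ --seed 1
alpskit simulate cohort  --out cohort/ --seed 1
alpskit tensor --dwi sim/dwi.nii.gz --bvals sim/bvals --bvecs sim/bvecs --out maps/
alpskit alps   --maps maps/ --rois sim/rois.json --out alps.tsv
alpskit wmh    --lesions lesions.nii.gz --rois sim/rois.json --xfm identity --out wmh.tsv
alpskit stats  --table cohort/cohort.csv --outcome alps_true --out ancova.json
alpskit run    --config run.yaml
```

A minimal end-to-end config:

```yaml
mode: synthetic
out_dir: out
seed: 7
synthetic:
  cohort: {n_ad: 16, n_hc: 18}
  phantom: {grid_shape: [32, 32, 32]}
  n_contaminated: 2
```

`alpskit run` writes `subjects.tsv` (everyone), `analyzed.tsv` (clean),
`excluded.tsv` (WMH-in-ROI subjects, analyzed separately), `stats.json` and a
`manifest.json` with filter counts and output checksums; identical
(config, seed) pairs produce byte-identical outputs.

## Conventions

- World coordinates are RAS millimetres; all distances go through the NIfTI
  affine, so anisotropic voxels are handled correctly.
- Sphere membership is voxel-center-in-sphere with inclusive boundary.
- Tensor components are stored lower-triangular (Dxx, Dxy, Dyy, Dxz, Dyz,
  Dzz) in the voxel frame and rotated to world axes before diagonals are read.
- The combined ALPS index is the mean of the hemispheric indices and is
  reported missing if either side is missing.
- A subject is flagged `excluded` if any of the four ROI spheres contains at
  least one thresholded lesion voxel (threshold 0.5, inclusive).
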