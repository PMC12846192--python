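# magwire

Single-view 3-D reconstruction of an interventional guidewire that fuses
two modalities: a **monocular relative-depth** profile along the wire
(correct ordering, ambiguous and smoothly distorted scale) and
**tri-axial readings of a fixed 4×4 planar magnetic sensor array**
(absolute pose information through the point-dipole law). A magnetic
encoder–decoder corrects the depth; a KNN + cross-attention fusion block
and a PointNet-style per-point regressor predict the 3-D centerline.

Because no public paired dataset of guidewire images and magnetic array
readings exists, the package ships a **physics-based synthetic phantom**
that generates centerlines, sensor frames, monocular depth profiles and
rendered projections consistently from a single seed. See
[docs/methods.md](docs/methods.md) for the full method description.

Everything is pure Python on numpy/scipy/scikit-image, including a small
reverse-mode autodiff engine and Adam optimizer (`magwire.autodiff`,
`magwire.nn`) — no deep-learning framework required. All runs are
single-threaded deterministic: a run directory is a pure function of its
config and seed.

## Quick start (Python)

```python
from magwire.pipeline import ExperimentConfig, run_experiment

res = run_experiment(ExperimentConfig(seed=1, output_dir="runs/demo"))
print(res["report"])        # test-split RMSE / MAE / MAE_z / Hausdorff in mm
```

The default **desk** profile (300 samples, 64 points, 64×64 field grid,
60 epochs per stage) finishes in a few minutes on one CPU core.
`ExperimentConfig.paper_faithful()` switches to the full-scale recipe
(128 points, 256×256 grid → 65 536-long field vectors, 200 epochs).

## Quick start (CLI)

```bash
magwire simulate      --set seed=1 --set n_samples=300 --out runs/data
magwire train-encoder --set seed=1 --dataset runs/data --out runs/encoder.npz
magwire train-fusion  --set seed=1 --dataset runs/data --encoder runs/encoder.npz --out-dir runs/full
magwire evaluate      --set seed=1 --out-dir runs/e2e        # all stages in one go
magwire reconstruct   --run-dir runs/e2e --sample-index 0 --out pred.csv
magwire ablation      --set seed=1 --out-dir runs/ablation   # base / +KNN / +attention / full
```

Commands accept `--config config.yaml` plus `--set key=value` overrides
for any `ExperimentConfig` field.

## Layout

| Path | Contents |
| --- | --- |
| `src/magwire/geometry.py` | intrinsics, back-projection, centerline resampling/normalization, CSV/PLY/depth-map I/O |
| `src/magwire/phantom.py` | synthetic generator: curvature-profile centerlines, dipole fields, sensor frames, depth simulation, ×4 exact augmentation |
| `src/magwire/preprocess.py` | image padding/resizing, segmentation, ordered centerline extraction, field interpolation to a dense grid |
| `src/magwire/mag_encoder.py` | magnetic depth correction: MLP encoder–decoder, Chamfer + landmark-anchor loss, cumulative curve decoding |
| `src/magwire/fusion.py` | depth embeddings, KNN matching, cross-attention, PointNet-style regressor, weighted-MAE training |
| `src/magwire/metrics.py` | RMSE, MAE, MAE_z, Hausdorff, report/CSV emission |
| `src/magwire/pipeline.py`, `cli.py` | experiment orchestration, ablation grid, YAML/CLI front end |
| `src/magwire/autodiff.py`, `nn.py` | numpy reverse-mode autodiff, Linear/BatchNorm/MLP, Adam |
| `tests/test_acceptance.py` | one test per acceptance criterion |
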