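# Methods

`magwire` reconstructs the 3-D centerline of an interventional guidewire
from a single projection view by fusing two complementary observations:

* a **monocular relative depth** profile along the wire, which carries
  the depth *ordering* but is scale/shift-ambiguous and smoothly
  distorted, and
* **tri-axial readings of a fixed 4×4 planar magnetic sensor array**,
  which respond to the wire's absolute pose — in particular its height
  above the array — through the point-dipole law.

Because no public paired dataset of guidewire images and magnetic array
readings exists, the package ships a physics-based synthetic phantom
that generates all modalities consistently from a single seed.

## 1. Geometry and conventions

The camera sits at the origin looking along +z; lengths are mm, fields
µT, dipole moments A·m². A pixel `(u, v)` is 0-based `(column, row)`
with integer pixel centers. Back-projection lifts a pixel with depth
`D(u, v)` through the inverse intrinsics:

```
p = D(u, v) · K⁻¹ (u, v, 1)ᵀ
```

A guidewire is an ordered polyline (tip first) of `N` points
(`CenterlineCloud`). For learning, clouds are normalized per sample by
centroid-centering and unit-max-radius scaling; the similarity record is
kept so evaluation happens in mm.

## 2. Synthetic phantom

**Centerlines.** Four shape families (left bend, right bend, large left
curvature, S-shape) are generated by integrating a signed curvature
profile at uniform arc-length steps, modulated by a small seeded smooth
jitter, then posed rigidly in the camera frame (restricted in-plane
rotation — the insertion port fixes the heading — plus a depth tilt and
a translation).

**Magnetics.** The wire is magnetized along its axis: dipoles at
arc-length fractions 0, ½, 1 carry moments along the local tangent with
graded magnitudes (0.9/0.5/0.25 A·m², tip strongest). The grading gives
the array's field pattern a handedness that identifies the tip; with
identical axial moments the field is nearly symmetric under reversing
the wire and the point ordering is unlearnable. Each of the 16 sensors
reads the superposed dipole fields

```
B(r) = (µ0/4π) (3(m·r̂)r̂ − m) / |r|³
```

plus seeded Gaussian noise. A negative-control switch replaces the
readings with pure noise of matched magnitude.

**Monocular depth.** The relative-depth observation is
`z_img = s·(z + d) + t + ε` with per-sample scale `s` and shift `t`, a
smooth non-affine distortion `d` (seeded low-frequency sinusoid along
the wire, amplitude 0.4× the depth spread), and white noise ε. The
distortion matters: an affine-plus-white-noise observation is fully
repaired by per-sample standardization, leaving the magnetic channel
nothing to correct, which contradicts the premise that monocular depth
is unreliable along the optical axis. Smooth structured error is what
monocular depth networks actually produce and what the magnetic channel
can fix.

**Augmentation.** Each sample expands ×4 (original, horizontal flip,
rotation about the camera axis, isotropic scale), so 282 base samples
yield 1128. All transforms are physically exact: under the flip the
field transforms as a pseudovector `(Bx, By, Bz) → (Bx, −By, −Bz)` at
the mirrored sensor; under rotation the clean field is re-simulated for
the rotated scene and the measured noise residual is rotated as a
vector; under scale `s` coordinates and depths scale by `s` and dipole
readings by `s⁻³`. Tests verify each transform against re-simulation.

## 3. Preprocessing

Images are padded symmetrically to a square (median fill) and
bilinearly resized to 512×512 with an exact coordinate-map record. The
dark, slender wire is segmented by intensity thresholding (Otsu default)
keeping the largest connected component; the mask's morphological
skeleton must be a simple open curve (exactly two endpoints), traversed
from the endpoint nearer the image border.

The 16 tri-axial readings are bilinearly interpolated per axis over the
array plane onto a dense regular grid and flattened (default: per-node
magnitude |B|; 256×256 → 65 536 at the faithful profile, 64×64 → 4 096
at desk scale). The per-node magnitude outperformed stacking the three
signed components in controlled runs (median rank correlation of the
recovered depth 0.80 vs 0.51), so it is the default. Inputs to the
encoder are signed-log compressed and standardized with training-split
statistics that travel with the checkpoint.

## 4. Magnetic depth correction (encoder–decoder)

An MLP encoder (linear → batch norm → leaky-ReLU stacks) compresses the
field vector to a 256-wide latent; a decoder expands it to an N×3 cloud
in normalized coordinates, whose z-column, min-max scaled to [0, 1], is
the corrected depth `z_mag = f_dec(f_enc(B))`.

Training minimises the Chamfer distance (squared bidirectional mean)

```
CD = (1/|A|) Σ_a min_b ‖a−b‖² + (1/|B|) Σ_b min_a ‖a−b‖²
```

between the decoded cloud and the normalized ground truth. Two measures
reconcile this unordered-set loss with the ordered-curve target:

* **Cumulative decoding.** The decoder's raw outputs are per-point
  displacements whose re-centered running sum forms the curve, so
  consecutive decoded points are neighbours by construction. With a
  plain (absolute) decoder, Chamfer training converges to an unordered
  mid-curve blur: measured correlation between decoded index and
  nearest-ground-truth index was ≈ 0.02.
* **Landmark anchoring.** Chamfer is invariant to reversing the curve,
  so the decoded traversal direction is unidentifiable from it. A small
  squared-error term at five arc-length landmarks (fractions 0, ¼, ½,
  ¾, 1) breaks the reversal symmetry and pins the index correspondence.
  Without it, per-sample rank correlations between `z_mag` and true z
  were mixed-sign (±0.4); with it they are consistently positive.

Training uses Adam (decoupled weight decay), batch 4, an internal 7:3
train/validation split, and returns the parameters with the best
validation objective. Everything is seeded and single-threaded
deterministic.

## 5. Fusion and regression

Per point, scalar `z_img` (standardized per sample) and `z_mag` are
embedded into D=64 dimensions by independent linear maps. Three feature
blocks are concatenated per point and fed to a shared local MLP:

* **fused embedding** — an affine layer on the concatenated pair
  (always present);
* **cross-attention block** — queries from the magnetic embeddings,
  keys/values from the image embeddings,
  `A = softmax(Q Kᵀ / √F)`, output `A V` (F = 128);
* **KNN block** — for each magnetic embedding, the mean of its k = 4
  nearest image embeddings (ties broken by lower index).

Composition is *additive*: disabled blocks are zeroed, never
substituted, so attention/KNN can only add information on top of the
per-point fused pathway. (A replacement design, where attention output
displaced the fused embedding, made the attention variants strictly
worse than the base at desk scale: test MAE_z 5.96 vs 3.19 mm.)

A PointNet-style regressor — shared per-point MLP, max-pooled global
feature concatenated back to every point — predicts normalized
coordinates, trained with a weighted MAE that up-weights depth:
weights (1, 1, 5). The 2×2 ablation grid (base / +KNN / +attention /
full) shares the dataset, encoder and splits across rows.

## 6. Metrics

With `d_i = ‖P_i − P̂_i‖` over index-aligned points: RMSE is the
quadratic mean of `d_i`, MAE the arithmetic mean, MAE_z the mean
absolute z-difference; the Hausdorff distance is the bidirectional
worst-case nearest-neighbour distance. Evaluation happens in mm after
undoing the per-sample normalization with the ground-truth record.

## 7. Experiment profiles and reproducibility

The **desk** profile (default: 300 samples, N=64, 64×64 field grid,
60 epochs per stage) runs end to end in minutes on one CPU core. The
**paper-faithful** profile keeps N=128, the 256×256 grid (65 536-long
field vectors), 200 epochs and learning rates 1e-4/1e-3. All
randomness descends from one master seed through a counter scheme
(`SeedSequence([master, stage])`), so a run directory — config,
manifest, checkpoints, per-epoch CSV logs, metrics report — is a pure
function of its config.

At desk scale (seed 1), the fused model reaches test MAE_z ≈ 3.4 mm vs
≈ 4.0 mm for the image-only baseline, and the ablation orders
base > +KNN > +attention > full (medians 2.76 / 2.60 / 2.30 / 2.12 mm),
i.e. each module helps and the full model is best.
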