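"""Forward simulator for the guidewire acquisition platform.

Generates the three ingredients a training sample needs:

* smooth guidewire centerlines from four shape families (left bend,
  right bend, large left curvature, S-shape), posed in the camera frame;
* scale/shift-ambiguous monocular depth observations (an affine map of
  true depth plus a smooth non-affine distortion and Gaussian noise,
  emulating relative-depth networks);
* tri-axial readings of a fixed 4x4 planar magnetic sensor array.

The guidewire is magnetised along its axis: it carries small magnetic
dipoles (by default at its tip, midpoint and tail) whose moments point
along the local tangent, strongest at the tip.  The array reading
therefore varies with the wire's pose -- in particular with its height
above the sensor plane, the physical channel that resolves the
monocular depth ambiguity -- and the graded, tangent-aligned moments
make the field pattern informative about the wire's shape and tip
direction.  Fields follow the point-dipole law, B proportional to
1/r^3.

Geometry convention: camera at the origin looking along +z (depth); the
sensor array lies in the plane z = array_z below the wire, centered on
the optical axis.  Lengths in mm, fields in microtesla (uT), moments in
A*m^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import CameraIntrinsics, CenterlineCloud, project_points

__all__ = [
    "FAMILIES",
    "ShapeSpec",
    "RigidPose",
    "DipoleSource",
    "SensorFrame",
    "Sample",
    "Dataset",
    "default_sensor_layout",
    "default_intrinsics",
    "generate_curve",
    "dipole_field",
    "simulate_sensor_frame",
    "simulate_relative_depth",
    "augment_sample",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "render_guidewire_image",
]

FAMILIES = ("left_bend", "right_bend", "large_left_curvature", "s_shape")

MU0_OVER_4PI_MM_UT = 1e8  # (mu0/4pi) * (A*m^2 / mm^3) expressed in uT


@dataclass(frozen=True)
class RigidPose:
    """Placement of a curve's local (u, v) plane in the camera frame.

    ``u`` maps to a horizontal direction (rotated about the camera axis
    by ``psi``), ``v`` maps to a mostly-depth direction tilted from +z
    by ``tilt``; the curve centroid lands at ``center``.
    """

    psi: float = 0.0
    tilt: float = 0.0
    center: tuple = (0.0, 0.0, 180.0)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        cp, sp = np.cos(self.psi), np.sin(self.psi)
        ct, st = np.cos(self.tilt), np.sin(self.tilt)
        e_u = np.array([cp, sp, 0.0])
        e_v = np.array([sp * st, -cp * st, ct])
        return e_u, e_v


@dataclass(frozen=True)
class ShapeSpec:
    family: str
    curvature_scale: float = 1.0
    length_mm: float = 80.0
    pose: RigidPose = field(default_factory=RigidPose)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}; expected one of {FAMILIES}")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")


def _curvature_profile(spec: ShapeSpec, s: np.ndarray) -> np.ndarray:
    """Signed planar curvature kappa(s) in rad/mm for each family."""
    L = spec.length_mm
    base = 0.9 / L  # total turn ~0.9 rad at unit curvature_scale
    c = base * spec.curvature_scale
    if spec.family == "left_bend":
        return np.full_like(s, -c)
    if spec.family == "right_bend":
        return np.full_like(s, c)
    if spec.family == "large_left_curvature":
        return np.full_like(s, -2.5 * c)
    # s_shape: linear profile crossing zero exactly once at mid-length
    return 1.8 * c * (2.0 * s / L - 1.0)


def generate_curve(spec: ShapeSpec, seed: int = 0, n_points: int = 128) -> CenterlineCloud:
    """Generate a smooth centerline of the requested family.

    The curve is integrated from its signed curvature profile at equal
    arc-length steps (so samples are uniformly spaced along the wire),
    modulated by a small smooth multiplicative jitter (seeded) that
    varies stiffness without altering the sign pattern of the curvature,
    then posed in the camera frame.  Point 0 is the tip.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, spec.length_mm, n_points)
    kappa = _curvature_profile(spec, s)
    # smooth positive modulation: 1 + 0.05 * sin(2*pi*s/L + phase)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    kappa = kappa * (1.0 + 0.05 * np.sin(2.0 * np.pi * s / spec.length_mm + phase))
    ds = s[1] - s[0]
    theta = np.concatenate([[0.0], np.cumsum(0.5 * (kappa[1:] + kappa[:-1]) * ds)])
    u = np.concatenate([[0.0], np.cumsum(0.5 * (np.cos(theta[1:]) + np.cos(theta[:-1])) * ds)])
    v = np.concatenate([[0.0], np.cumsum(0.5 * (np.sin(theta[1:]) + np.sin(theta[:-1])) * ds)])
    u -= u.mean()
    v -= v.mean()
    e_u, e_v = spec.pose.axes()
    pts = np.asarray(spec.pose.center) + np.outer(u, e_u) + np.outer(v, e_v)
    return CenterlineCloud(pts)


# -- magnetic model ----------------------------------------------------------


@dataclass(frozen=True)
class DipoleSource:
    """Point magnetic dipole: position in mm, moment in A*m^2."""

    position: tuple
    moment: tuple = (0.0, 0.0, 0.5)
    noise_sd: float = 0.0  # per-axis sensor noise sd, uT

    def __post_init__(self):
        if not np.any(np.asarray(self.moment)):
            raise ValueError("dipole moment must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def dipole_field(source: DipoleSource, at) -> np.ndarray:
    """Noiseless point-dipole field at a location, in uT.

    B(r) = (mu0 / 4 pi) * (3 (m . r_hat) r_hat - m) / |r|^3
    """
    r = np.asarray(at, dtype=np.float64) - np.asarray(source.position, dtype=np.float64)
    d = np.linalg.norm(r)
    if d == 0:
        raise ValueError("field evaluation point coincides with the dipole position")
    rhat = r / d
    m = np.asarray(source.moment, dtype=np.float64)
    return MU0_OVER_4PI_MM_UT * (3.0 * np.dot(m, rhat) * rhat - m) / d**3


@dataclass
class SensorFrame:
    """One reading of the 4x4 planar tri-axial array.

    ``positions``: (16, 3) sensor locations in mm; ``readings``: (16, 3)
    (Bx, By, Bz) in uT, row-paired with positions.
    """

    positions: np.ndarray
    readings: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.readings = np.asarray(self.readings, dtype=np.float64)
        if self.positions.shape != (16, 3) or self.readings.shape != (16, 3):
            raise ValueError("a SensorFrame holds exactly 16 sensors with 3-axis readings")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.readings))):
            raise ValueError("positions and readings must be finite")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sensor_id,x,y,z,Bx,By,Bz\n")
            for i, (p, b) in enumerate(zip(self.positions, self.readings)):
                fh.write(f"{i},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g},{b[0]:.12g},{b[1]:.12g},{b[2]:.12g}\n")

    @classmethod
    def from_csv(cls, path) -> "SensorFrame":
        raw = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(raw[:, 1:4], raw[:, 4:7])


def default_sensor_layout(pitch_mm: float = 30.0, array_z: float = 260.0) -> np.ndarray:
    """4x4 grid centered on the optical axis in the plane z = array_z."""
    coords = (np.arange(4) - 1.5) * pitch_mm
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    pos = np.column_stack([xx.ravel(), yy.ravel(), np.full(16, array_z)])
    return pos


def default_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=700.0, fy=700.0, cx=256.0, cy=256.0)


def simulate_sensor_frame(
    sources,
    layout: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SensorFrame, np.ndarray]:
    """Superpose dipole fields at each sensor and add Gaussian noise.

    Returns ``(frame, clean_readings)`` where ``clean_readings`` is the
    noiseless field (kept so augmentations can transform signal and
    noise exactly).
    """
    if isinstance(sources, DipoleSource):
        sources = [sources]
    layout = np.asarray(layout, dtype=np.float64)
    clean = np.zeros((len(layout), 3))
    for src in sources:
        for j, p in enumerate(layout):
            clean[j] += dipole_field(src, p)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else np.zeros_like(clean)
    return SensorFrame(layout.copy(), clean + noise), clean


def simulate_relative_depth(
    cloud: CenterlineCloud,
    K: CameraIntrinsics = None,
    ambiguity: tuple = (1.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    distortion_rel: float = 0.0,
) -> np.ndarray:
    """Emulate a relative-depth network's per-point output.

    ``z_img[i] = scale * (z_true[i] + d[i]) + shift + N(0, noise_sd^2)``
    -- an affine observation that carries no metric scale, corrupted by
    a smooth structured distortion ``d``: a seeded low-frequency
    sinusoid along the wire whose amplitude is ``distortion_rel`` times
    the true depth spread.  Monocular relative-depth estimates err
    smoothly and non-affinely, which is exactly the error a per-sample
    affine/standardising correction cannot remove -- the failure mode
    the magnetic channel is there to fix.
    """
    scale, shift = ambiguity
    if scale <= 0:
        raise ValueError("ambiguity scale must be positive")
    if distortion_rel < 0:
        raise ValueError("distortion_rel must be nonnegative")
    z = cloud.points[:, 2]
    if np.any(z <= 0):
        raise ValueError("all true depths must be positive")
    rng = np.random.default_rng(seed)
    d = 0.0
    if distortion_rel > 0:
        t = np.linspace(0.0, 1.0, z.shape[0])
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        d = distortion_rel * z.std() * np.sin(2.0 * np.pi * freq * t + phase)
    eps = rng.normal(0.0, noise_sd, size=z.shape) if noise_sd > 0 else 0.0
    return scale * (z + d) + shift + eps


# -- samples and datasets ----------------------------------------------------


@dataclass
class Sample:
    """One paired observation: geometry, depth observation, magnetics."""

    cloud: CenterlineCloud
    z_img: np.ndarray
    frame: SensorFrame
    frame_clean: np.ndarray
    sources: list
    spec: ShapeSpec
    seed: int
    ambiguity: tuple = (1.0, 0.0)

    @property
    def n_points(self) -> int:
        return self.cloud.n_points


@dataclass
class Dataset:
    samples: list
    manifest: dict

    def split(self, name: str) -> list:
        idx = self.manifest["splits"][name]
        return [self.samples[i] for i in idx]

    def __len__(self):
        return len(self.samples)


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions for the synthetic platform."""

    n_points: int = 128
    sensor_pitch_mm: float = 30.0
    array_z_mm: float = 260.0
    source_fractions: tuple = (0.0, 0.5, 1.0)  # dipole positions along the wire
    moment_magnitudes: tuple = (0.9, 0.5, 0.25)  # A*m^2, along the local tangent
    field_noise_rel: float = 0.01  # per-axis sd as fraction of max |reading|
    depth_noise_sd: float = 0.5  # mm, on the observed (affine) depth
    depth_distortion_rel: float = 0.4  # smooth non-affine depth error, rel. to depth spread
    depth_scale_range: tuple = (0.6, 1.8)
    depth_shift_range: tuple = (-30.0, 30.0)
    curvature_scale_range: tuple = (0.7, 1.3)
    length_range: tuple = (60.0, 90.0)
    center_xy_range: tuple = (-15.0, 15.0)
    center_z_range: tuple = (160.0, 210.0)
    tilt_range: tuple = (-0.25, 0.25)
    psi_range: tuple = (-0.4, 0.4)  # in-plane rotation; insertion port fixes the heading
    magnetic_informative: bool = True  # False: pure-noise channel (negative control)


def _wire_sources(cloud: CenterlineCloud, config: SimulatorConfig) -> list:
    if len(config.source_fractions) != len(config.moment_magnitudes):
        raise ValueError("source_fractions and moment_magnitudes must pair up")
    s = cloud.arc_lengths()
    total = s[-1]
    tangents = np.gradient(cloud.points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    out = []
    for f, mag in zip(config.source_fractions, config.moment_magnitudes):
        target = f * total
        pos = np.array([np.interp(target, s, cloud.points[:, j]) for j in range(3)])
        t = np.array([np.interp(target, s, tangents[:, j]) for j in range(3)])
        t /= np.linalg.norm(t)
        out.append(DipoleSource(tuple(pos), tuple(mag * t)))
    return out


def _simulate_one(spec: ShapeSpec, config: SimulatorConfig, seed_seq: np.random.SeedSequence) -> Sample:
    child = seed_seq.generate_state(4, dtype=np.uint32)
    curve_seed, field_seed, depth_seed, amb_seed = (int(x) for x in child)
    cloud = generate_curve(spec, seed=curve_seed, n_points=config.n_points)
    layout = default_sensor_layout(config.sensor_pitch_mm, config.array_z_mm)
    sources = _wire_sources(cloud, config)
    frame, clean = simulate_sensor_frame(sources, layout, noise_sd=0.0)
    noise_sd = config.field_noise_rel * np.abs(clean).max()
    rng_f = np.random.default_rng(field_seed)
    if config.magnetic_informative:
        noise = rng_f.normal(0.0, noise_sd, size=clean.shape)
        frame = SensorFrame(layout, clean + noise)
    else:
        # negative control: readings carry no information about the wire
        mag = np.abs(clean).max()
        frame = SensorFrame(layout, rng_f.normal(0.0, mag, size=clean.shape))
        clean = np.zeros_like(clean)
    rng_a = np.random.default_rng(amb_seed)
    scale = rng_a.uniform(*config.depth_scale_range)
    shift = rng_a.uniform(*config.depth_shift_range)
    z_img = simulate_relative_depth(
        cloud,
        ambiguity=(scale, shift),
        noise_sd=config.depth_noise_sd,
        seed=depth_seed,
        distortion_rel=config.depth_distortion_rel,
    )
    return Sample(cloud, z_img, frame, clean, sources, spec, seed=curve_seed, ambiguity=(scale, shift))


def augment_sample(sample: Sample, seed: int = 0, rot_deg: float = 15.0, scale_range: tuple = (0.9, 1.1)) -> list:
    """Expand one sample into four: original, flip, rotation, scaling.

    All modalities transform consistently and exactly:

    * horizontal flip (x -> -x): the field is a pseudovector, so at the
      mirrored sensor position (Bx, By, Bz) -> (Bx, -By, -Bz);
    * rotation about the camera axis: depth is unchanged; sensor
      positions and field vectors rotate together;
    * isotropic scale s: coordinates and depth observations scale by s,
      dipole readings by s^-3 (moments held fixed under the 1/r^3 law).
    """
    rng = np.random.default_rng(seed)
    angle = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    s = rng.uniform(*scale_range)
    return [sample, _flip(sample), _rotate(sample, angle), _scale(sample, s)]


def _flip(sample: Sample) -> Sample:
    M = np.diag([-1.0, 1.0, 1.0])
    B = np.diag([1.0, -1.0, -1.0])  # pseudovector under x-reflection
    cloud = CenterlineCloud(sample.cloud.points @ M)
    frame = SensorFrame(sample.frame.positions @ M, sample.frame.readings @ B)
    clean = sample.frame_clean @ B
    sources = [
        replace(src, position=tuple(np.asarray(src.position) @ M), moment=tuple(np.asarray(src.moment) @ B))
        for src in sample.sources
    ]
    return replace(sample, cloud=cloud, frame=frame, frame_clean=clean, sources=sources)


def _rotate(sample: Sample, angle: float) -> Sample:
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    cloud = CenterlineCloud(sample.cloud.points @ R.T)
    sources = [
        replace(src, position=tuple(R @ np.asarray(src.position)), moment=tuple(R @ np.asarray(src.moment)))
        for src in sample.sources
    ]
    # sensors stay fixed; re-evaluate the rotated scene's field and carry
    # the measured noise residual along (rotated as a field vector)
    _, clean = simulate_sensor_frame(sources, sample.frame.positions, noise_sd=0.0) if np.any(
        sample.frame_clean
    ) else (None, np.zeros_like(sample.frame_clean))
    noise = sample.frame.readings - sample.frame_clean
    frame = SensorFrame(sample.frame.positions, clean + noise @ R.T)
    return replace(sample, cloud=cloud, frame=frame, frame_clean=clean, sources=sources)


def _scale(sample: Sample, s: float) -> Sample:
    cloud = CenterlineCloud(sample.cloud.points * s)
    frame = SensorFrame(sample.frame.positions * s, sample.frame.readings / s**3)
    clean = sample.frame_clean / s**3
    sources = [replace(src, position=tuple(np.asarray(src.position) * s)) for src in sample.sources]
    return replace(
        sample,
        cloud=cloud,
        z_img=sample.z_img * s,
        frame=frame,
        frame_clean=clean,
        sources=sources,
        ambiguity=(sample.ambiguity[0] * s, sample.ambiguity[1] * s),
    )


def split_sizes(n: int, ratios: tuple = (7, 2, 1)) -> tuple[int, int, int]:
    total = sum(ratios)
    n_train = int(n * ratios[0] / total)
    n_val = int(n * ratios[1] / total)
    return n_train, n_val, n - n_train - n_val


def generate_dataset(
    n_samples: int,
    config: SimulatorConfig = None,
    master_seed: int = 0,
    augment: bool = False,
) -> Dataset:
    """Draw ``n_samples`` over the four families and split 7:2:1.

    Every random draw descends from ``master_seed`` through a counter
    scheme, so the dataset (and its manifest) is a pure function of the
    arguments.  With ``augment=True`` each base sample is expanded to 4.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    config = config or SimulatorConfig()
    if config.n_points < 2:
        raise ValueError("config.n_points must be >= 2")
    samples = []
    records = []
    for i in range(n_samples):
        ss = np.random.SeedSequence([master_seed, i])
        rng = np.random.default_rng(ss.generate_state(1)[0])
        family = FAMILIES[rng.integers(len(FAMILIES))]
        spec = ShapeSpec(
            family=family,
            curvature_scale=rng.uniform(*config.curvature_scale_range),
            length_mm=rng.uniform(*config.length_range),
            pose=RigidPose(
                psi=rng.uniform(*config.psi_range),
                tilt=rng.uniform(*config.tilt_range),
                center=(
                    rng.uniform(*config.center_xy_range),
                    rng.uniform(*config.center_xy_range),
                    rng.uniform(*config.center_z_range),
                ),
            ),
        )
        base = _simulate_one(spec, config, np.random.SeedSequence([master_seed, i, 1]))
        group = augment_sample(base, seed=int(np.random.SeedSequence([master_seed, i, 2]).generate_state(1)[0])) if augment else [base]
        for j, smp in enumerate(group):
            records.append(
                {
                    "index": len(samples),
                    "base_index": i,
                    "augmentation": ["original", "flip", "rotate", "scale"][j] if augment else "original",
                    "family": family,
                    "seed": smp.seed,
                    "curvature_scale": spec.curvature_scale,
                    "length_mm": spec.length_mm,
                }
            )
            samples.append(smp)
    n = len(samples)
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 10**6]).generate_state(1)[0])
    perm = rng.permutation(n)
    n_train, n_val, n_test = split_sizes(n)
    splits = {
        "train": sorted(int(k) for k in perm[:n_train]),
        "val": sorted(int(k) for k in perm[n_train : n_train + n_val]),
        "test": sorted(int(k) for k in perm[n_train + n_val :]),
    }
    for name, idx in splits.items():
        for k in idx:
            records[k]["split"] = name
    manifest = {
        "units": {"length": "mm", "field": "uT"},
        "master_seed": master_seed,
        "n_samples": n,
        "split_ratio": "7:2:1",
        "splits": splits,
        "samples": records,
    }
    return Dataset(samples, manifest)


def save_dataset(dataset: Dataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(dataset.manifest, indent=1, sort_keys=True))
    for i, smp in enumerate(dataset.samples):
        d = out / f"sample_{i:05d}"
        d.mkdir(exist_ok=True)
        smp.cloud.to_csv(d / "cloud.csv")
        np.savetxt(d / "depth.csv", smp.z_img, delimiter=",", header="z_img", comments="")
        smp.frame.to_csv(d / "sensors.csv")
        meta = {
            "family": smp.spec.family,
            "seed": smp.seed,
            "ambiguity_scale": smp.ambiguity[0],
            "ambiguity_shift": smp.ambiguity[1],
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_dataset(in_dir) -> Dataset:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    samples = []
    for i in range(manifest["n_samples"]):
        d = src / f"sample_{i:05d}"
        cloud = CenterlineCloud.from_csv(d / "cloud.csv")
        z_img = np.loadtxt(d / "depth.csv", delimiter=",", skiprows=1)
        frame = SensorFrame.from_csv(d / "sensors.csv")
        meta = json.loads((d / "meta.json").read_text())
        samples.append(
            Sample(
                cloud,
                z_img,
                frame,
                frame.readings.copy(),
                [],
                ShapeSpec(meta["family"]),
                seed=meta["seed"],
                ambiguity=(meta["ambiguity_scale"], meta["ambiguity_shift"]),
            )
        )
    return Dataset(samples, manifest)


def render_guidewire_image(
    cloud: CenterlineCloud,
    K: CameraIntrinsics,
    shape: tuple = (1536, 2048),
    wire_radius_px: float = 4.0,
    foreground: int = 10,
    background: int = 200,
) -> np.ndarray:
    """Rasterise a dark guidewire on a bright background (uint8 H x W)."""
    from skimage.draw import disk

    img = np.full(shape, background, dtype=np.uint8)
    pixels, _ = project_points(cloud, K)
    # densify so consecutive disks overlap
    dense = []
    for a, b in zip(pixels[:-1], pixels[1:]):
        steps = max(2, int(np.ceil(np.linalg.norm(b - a) / max(wire_radius_px / 2.0, 0.5))))
        t = np.linspace(0.0, 1.0, steps)
        dense.append(a[None] * (1 - t)[:, None] + b[None] * t[:, None])
    for u, v in np.vstack(dense):
        rr, cc = disk((v, u), wire_radius_px, shape=shape)
        img[rr, cc] = foreground
    return img
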