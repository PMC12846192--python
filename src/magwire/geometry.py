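"""Camera model, back-projection and centerline geometry.

The guidewire is represented as an ordered 3-D polyline (tip to tail) in
millimetres, in the camera coordinate frame: the camera sits at the
origin looking along +z, so a point's z coordinate is its depth.

A pixel ``(u, v)`` is 0-based, in (column, row) order, with pixel centers
at integer coordinates.  Back-projection maps a pixel and a depth through
the inverse intrinsic matrix to a camera-frame point,
``p = D(u, v) * K^{-1} (u, v, 1)^T``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "CenterlineCloud",
    "DepthMap",
    "NormalizationRecord",
    "backproject",
    "project_points",
    "resample_centerline",
    "normalize_cloud",
    "denormalize_cloud",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def K_inv(self) -> np.ndarray:
        return np.array(
            [
                [1.0 / self.fx, 0.0, -self.cx / self.fx],
                [0.0, 1.0 / self.fy, -self.cy / self.fy],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass
class CenterlineCloud:
    """Ordered N x 3 guidewire centerline, tip first, coordinates in mm."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.points.shape[0] < 2:
            raise ValueError("a centerline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def total_length(self) -> float:
        return float(self.arc_lengths()[-1])

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path) -> None:
        header = "x,y,z"
        np.savetxt(path, self.points, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "CenterlineCloud":
        pts = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(np.atleast_2d(pts))

    def to_ply(self, path) -> None:
        buf = io.StringIO()
        buf.write("ply\nformat ascii 1.0\n")
        buf.write(f"element vertex {self.n_points}\n")
        buf.write("property float x\nproperty float y\nproperty float z\n")
        buf.write("end_header\n")
        for x, y, z in self.points:
            buf.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_ply(cls, path) -> "CenterlineCloud":
        with open(path) as fh:
            lines = fh.read().splitlines()
        start = lines.index("end_header") + 1
        pts = np.array([[float(v) for v in ln.split()] for ln in lines[start:] if ln])
        return cls(pts)


@dataclass
class DepthMap:
    """H x W grid of nonnegative relative depths with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("depth map must be 2-D")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("depths must be finite where valid")

    @property
    def shape(self):
        return self.values.shape

    def save(self, path) -> None:
        np.save(path, np.where(self.valid_mask, self.values, np.nan))

    @classmethod
    def load(cls, path) -> "DepthMap":
        vals = np.load(path)
        return cls(np.nan_to_num(vals), np.isfinite(vals))

    def to_png16(self, path) -> None:
        """Export a 16-bit PNG for visualisation (min-max scaled)."""
        import imageio.v3 as iio

        v = self.values[self.valid_mask]
        lo, hi = (v.min(), v.max()) if v.size else (0.0, 1.0)
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        img = np.zeros(self.values.shape, dtype=np.uint16)
        img[self.valid_mask] = ((self.values[self.valid_mask] - lo) * scale).astype(
            np.uint16
        )
        iio.imwrite(path, img)


def backproject(
    depth: DepthMap, pixels, K: CameraIntrinsics
) -> CenterlineCloud:
    """Lift pixels with depths to 3-D camera-frame points.

    Depth is sampled at the nearest pixel.  Raises ``IndexError`` naming
    the first pixel outside the grid or on the invalid mask.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    H, W = depth.shape
    pts = np.empty((len(pixels), 3))
    Kinv = K.K_inv
    for i, (u, v) in enumerate(pixels):
        r, c = int(round(v)), int(round(u))
        if not (0 <= r < H and 0 <= c < W):
            raise IndexError(f"pixel {i} at ({u}, {v}) lies outside the depth grid")
        if not depth.valid_mask[r, c]:
            raise IndexError(f"pixel {i} at ({u}, {v}) falls on the invalid mask")
        pts[i] = depth.values[r, c] * (Kinv @ np.array([u, v, 1.0]))
    return CenterlineCloud(pts)


def project_points(cloud: CenterlineCloud, K: CameraIntrinsics):
    """Perspective projection; returns (pixels (N,2), depths (N,))."""
    p = cloud.points
    z = p[:, 2]
    bad = np.flatnonzero(z <= 0)
    if bad.size:
        raise ValueError(f"point {bad[0]} has nonpositive depth z={z[bad[0]]}")
    u = K.fx * p[:, 0] / z + K.cx
    v = K.fy * p[:, 1] / z + K.cy
    return np.column_stack([u, v]), z.copy()


def resample_centerline(cloud: CenterlineCloud, n: int) -> CenterlineCloud:
    """Resample to exactly ``n`` points at equal arc-length spacing.

    Endpoints are preserved; interior points are linearly interpolated
    along the polyline.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    s = cloud.arc_lengths()
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate zero-length polyline")
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for j in range(3):
        out[:, j] = np.interp(targets, s, cloud.points[:, j])
    out[0] = cloud.points[0]
    out[-1] = cloud.points[-1]
    return CenterlineCloud(out)


@dataclass(frozen=True)
class NormalizationRecord:
    """Similarity transform taking normalized coordinates back to mm:
    ``p_mm = centroid + scale * p_norm``.
    """

    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0


def normalize_cloud(cloud: CenterlineCloud):
    """Center at the centroid and scale so max radius is 1.

    Returns ``(normalized cloud, record)`` where the record inverts the
    transform exactly.  Chamfer-supervised training needs scale-stable
    targets; evaluation in mm uses the record to undo the transform.
    """
    c = cloud.points.mean(axis=0)
    centered = cloud.points - c
    r = float(np.linalg.norm(centered, axis=1).max())
    if r <= 0:
        raise ValueError("all points identical: normalization scale is zero")
    return CenterlineCloud(centered / r), NormalizationRecord(c, r)


def denormalize_cloud(cloud: CenterlineCloud, record: NormalizationRecord) -> CenterlineCloud:
    return CenterlineCloud(record.centroid + record.scale * cloud.points)
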