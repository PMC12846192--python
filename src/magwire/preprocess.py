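"""Image and magnetic-field preprocessing.

Image side: symmetric padding to a square, bilinear resize to 512x512,
intensity-threshold guidewire segmentation (the wire is dark and slender
on a bright background), and ordered centerline extraction from the
segmentation's morphological skeleton.

Magnetic side: the 16 tri-axial readings of the 4x4 array are bilinearly
interpolated per axis over the array plane onto a dense regular grid and
flattened into the fixed-length vector the depth-correction encoder
consumes (default 256 x 256 -> 65536 magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage.measure import label
from skimage.morphology import skeletonize
from skimage.transform import resize

from .phantom import SensorFrame

__all__ = [
    "FieldVector",
    "GuidewireMask",
    "ResizeRecord",
    "pad_and_resize",
    "threshold_segment",
    "otsu_threshold",
    "extract_ordered_centerline",
    "interpolate_field",
    "field_interpolator",
]


@dataclass
class FieldVector:
    """Dense interpolated magnetic representation, flattened row-major."""

    values: np.ndarray
    grid_shape: tuple

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def __len__(self):
        return self.values.size

    def save(self, path) -> None:
        np.save(path, self.values.reshape(-1, *self.grid_shape) if self.values.size != np.prod(self.grid_shape) else self.values.reshape(self.grid_shape))

    @classmethod
    def load(cls, path) -> "FieldVector":
        arr = np.load(path)
        return cls(arr.ravel(), tuple(arr.shape[-2:]))


@dataclass
class GuidewireMask:
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())

    def to_png(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, (self.mask * 255).astype(np.uint8))


@dataclass(frozen=True)
class ResizeRecord:
    """Exact coordinate map between the output 512x512 raster and the input.

    ``pad_top`` rows of padding were added above the image, then the
    ``side x side`` square was resized to ``out_side``; pixel centers
    follow the half-pixel alignment of bilinear resampling.
    """

    pad_top: int
    side: int
    out_side: int
    in_shape: tuple

    def out_to_in(self, pixels: np.ndarray) -> np.ndarray:
        """Map (col, row) output pixels to input-image coordinates."""
        p = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
        s = self.side / self.out_side
        cols = (p[:, 0] + 0.5) * s - 0.5
        rows = (p[:, 1] + 0.5) * s - 0.5 - self.pad_top
        return np.column_stack([cols, rows])

    def in_to_out(self, pixels: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
        s = self.out_side / self.side
        cols = (p[:, 0] + 0.5) * s - 0.5
        rows = (p[:, 1] + 0.5 + self.pad_top) * s - 0.5
        return np.column_stack([cols, rows])


def pad_and_resize(image: np.ndarray, out_side: int = 512):
    """Pad the height symmetrically to a square, then bilinear-resize.

    The pad fill is the image's median intensity, which keeps the padded
    border away from the dark-wire tail of the histogram.  Returns
    ``(resized float array, ResizeRecord)``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    H, W = img.shape
    if W < H:
        raise ValueError("expected a landscape image (W >= H)")
    pad_total = W - H
    pad_top = pad_total // 2
    pad_bottom = pad_total - pad_top
    fill = float(np.median(img))
    padded = np.pad(img, ((pad_top, pad_bottom), (0, 0)), constant_values=fill)
    out = resize(padded, (out_side, out_side), order=1, anti_aliasing=False, preserve_range=True)
    return out, ResizeRecord(pad_top, W, out_side, (H, W))


def otsu_threshold(image: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(image)))


def threshold_segment(image: np.ndarray, threshold: float = None) -> GuidewireMask:
    """Segment the dark guidewire: ``intensity <= threshold``, keeping
    only the largest connected component.
    """
    img = np.asarray(image, dtype=np.float64)
    if threshold is None:
        threshold = otsu_threshold(img)
    raw = img <= threshold
    if not raw.any():
        raise ValueError(
            f"threshold {threshold} selects no pixels (image min {img.min()}); raise the threshold"
        )
    labels = label(raw, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return GuidewireMask(labels == counts.argmax())


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def extract_ordered_centerline(mask: GuidewireMask) -> np.ndarray:
    """Skeletonise the mask and return the centerline as an ordered
    (n, 2) array of (col, row) pixels.

    The skeleton must be a simple open curve: exactly two degree-1
    pixels.  Traversal starts from the endpoint closer to the image
    border (a proxy for the insertion tail being near the edge), and the
    chain is the shortest 8-connected skeleton path between endpoints.
    """
    skel = skeletonize(mask.mask)
    pts = {tuple(p) for p in np.argwhere(skel)}
    if not pts:
        raise ValueError("empty skeleton")
    degree = {p: sum((p[0] + dr, p[1] + dc) in pts for dr, dc in _NEIGHBORS) for p in pts}
    endpoints = [p for p, d in degree.items() if d == 1]
    if len(endpoints) != 2:
        raise ValueError(
            f"skeleton has {len(endpoints)} endpoints (need exactly 2); loops or branches present"
        )
    H, W = mask.mask.shape
    endpoints.sort(key=lambda p: (min(p[0], p[1], H - 1 - p[0], W - 1 - p[1]), p))
    start, goal = endpoints
    # BFS shortest path through the skeleton
    prev = {start: None}
    queue = [start]
    qi = 0
    while qi < len(queue):
        cur = queue[qi]
        qi += 1
        if cur == goal:
            break
        for dr, dc in _NEIGHBORS:
            nxt = (cur[0] + dr, cur[1] + dc)
            if nxt in pts and nxt not in prev:
                prev[nxt] = cur
                queue.append(nxt)
    if goal not in prev:
        raise ValueError("skeleton endpoints are not connected")
    chain = []
    cur = goal
    while cur is not None:
        chain.append(cur)
        cur = prev[cur]
    chain.reverse()
    return np.array([(c, r) for r, c in chain], dtype=np.float64)


def _grid_axes(frame: SensorFrame):
    """Recover the array's local 4x4 grid structure.

    Returns ``(u_levels, v_levels, basis, origin, order)`` where
    ``order[i, j]`` is the sensor index at grid node (i, j).  Raises if
    the sensors do not form a regular 4x4 grid in their own plane.
    """
    pos = frame.positions
    if np.ptp(pos[:, 2]) == 0.0:
        # axis-aligned planar layout: use x, y directly (keeps node
        # coordinates bit-exact)
        origin = np.array([0.0, 0.0, pos[0, 2]])
        basis_xy = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        q = pos[:, :2].copy()
        plane = basis_xy
        centered = pos - origin
    else:
        origin = pos.mean(axis=0)
        centered = pos - origin
        # in-plane coordinates (the grid's covariance is isotropic
        # in-plane, so only the normal direction is informative here)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        plane = vt[:2]
        q = centered @ plane.T
    # lattice axes: from a corner sensor to its nearest neighbour
    corner = int(np.argmax(np.linalg.norm(q, axis=1)))
    d = np.linalg.norm(q - q[corner], axis=1)
    d[corner] = np.inf
    a1 = q[int(np.argmin(d))] - q[corner]
    a1 /= np.linalg.norm(a1)
    a2 = np.array([-a1[1], a1[0]])
    rot = np.vstack([a1, a2])
    uv = q @ rot.T
    basis = rot @ plane
    span = np.abs(uv).max()

    # cluster coordinates into 4 levels per axis
    def levels(coords):
        srt = np.sort(coords)
        groups = [[srt[0]]]
        for c in srt[1:]:
            if c - groups[-1][-1] > span * 1e-4:
                groups.append([c])
            else:
                groups[-1].append(c)
        if len(groups) != 4:
            raise ValueError("sensors do not form a regular 4x4 grid")
        return np.array([np.mean(g) for g in groups])

    u_levels = levels(uv[:, 0])
    v_levels = levels(uv[:, 1])
    for lev in (u_levels, v_levels):
        gaps = np.diff(lev)
        if not np.allclose(gaps, gaps[0], rtol=1e-4):
            raise ValueError("sensor grid spacing is not constant")
    iu = np.argmin(np.abs(uv[:, 0][:, None] - u_levels[None]), axis=1)
    iv = np.argmin(np.abs(uv[:, 1][:, None] - v_levels[None]), axis=1)
    filled = np.full((4, 4), -1, dtype=int)
    for k, (a, b) in enumerate(zip(iu, iv)):
        if filled[a, b] != -1:
            raise ValueError("duplicate sensor grid positions")
        filled[a, b] = k
    order = filled
    return u_levels, v_levels, basis, origin, order


def field_interpolator(frame: SensorFrame, method: str = "linear"):
    """Per-axis interpolant of the array reading over the sensor plane.

    Returns ``(interp, (u_levels, v_levels))`` where ``interp(points_uv)``
    evaluates the 3-component field at local plane coordinates.
    """
    u_levels, v_levels, basis, origin, order = _grid_axes(frame)
    data = frame.readings[order]  # (4, 4, 3)
    rgi = RegularGridInterpolator(
        (u_levels, v_levels), data, method=method, bounds_error=False, fill_value=None
    )

    def interp(points_uv):
        return rgi(np.atleast_2d(points_uv))

    interp.basis = basis
    interp.origin = origin
    return interp, (u_levels, v_levels)


def interpolate_field(
    frame: SensorFrame,
    grid_shape: tuple = (256, 256),
    method: str = "linear",
    output: str = "magnitude",
) -> FieldVector:
    """Interpolate the sparse array reading to a dense flattened vector.

    Bilinear (or nearest) interpolation is applied to each axis
    component on a ``grid_shape`` lattice spanning the array extent;
    by default the per-node magnitude |B| is flattened row-major, giving
    length ``H * W`` (65536 at the default 256 x 256 grid).  With
    ``output='axes'`` the three components are stacked (length 3 H W).
    """
    interp, (u_levels, v_levels) = field_interpolator(frame, method=method)
    gu = np.linspace(u_levels[0], u_levels[-1], grid_shape[0])
    gv = np.linspace(v_levels[0], v_levels[-1], grid_shape[1])
    uu, vv = np.meshgrid(gu, gv, indexing="ij")
    vals = interp(np.column_stack([uu.ravel(), vv.ravel()]))  # (HW, 3)
    if output == "magnitude":
        flat = np.linalg.norm(vals, axis=1)
    elif output == "axes":
        flat = vals.T.ravel()
    else:
        raise ValueError("output must be 'magnitude' or 'axes'")
    return FieldVector(flat, tuple(grid_shape))
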