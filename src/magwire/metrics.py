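"""Reconstruction error metrics in millimetres.

RMSE and MAE are computed over index-aligned point pairs using the
per-point Euclidean distance d_i = ||P_i - P_hat_i|| (RMSE is the
quadratic mean of the d_i, MAE their arithmetic mean); MAE_axis takes
the absolute difference of a single coordinate; the Hausdorff distance
is the bidirectional worst-case nearest-neighbour distance and needs no
index alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "MetricsReport",
    "rmse",
    "mae_euclidean",
    "mae_axis",
    "hausdorff",
    "evaluate_pairs",
]

_AXES = {"x": 0, "y": 1, "z": 2}


def _pts(a) -> np.ndarray:
    p = a.points if hasattr(a, "points") else np.asarray(a, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("expected an (N, 3) point array")
    return p


def _aligned(pred, gt):
    p, g = _pts(pred), _pts(gt)
    if p.shape != g.shape:
        raise ValueError(f"point counts differ: {p.shape[0]} vs {g.shape[0]}")
    return p, g


def rmse(pred, gt) -> float:
    p, g = _aligned(pred, gt)
    d = np.linalg.norm(p - g, axis=1)
    return float(np.sqrt(np.mean(d**2)))


def mae_euclidean(pred, gt) -> float:
    p, g = _aligned(pred, gt)
    return float(np.mean(np.linalg.norm(p - g, axis=1)))


def mae_axis(pred, gt, axis: str = "z") -> float:
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    p, g = _aligned(pred, gt)
    j = _AXES[axis]
    return float(np.mean(np.abs(p[:, j] - g[:, j])))


def hausdorff(A, B) -> float:
    """Bidirectional Hausdorff distance between two point sets."""
    a, b = _pts(A), _pts(B)
    if a.size == 0 or b.size == 0:
        raise ValueError("Hausdorff distance of an empty set is undefined")
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


@dataclass
class MetricsReport:
    rmse_mm: float
    mae_mm: float
    mae_z_mm: float
    hd_mm: float
    n_samples: int

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def evaluate_pairs(pairs, per_sample_csv=None) -> MetricsReport:
    """Average the four metrics uniformly over (prediction, truth) pairs."""
    rows = []
    for pred, gt in pairs:
        rows.append(
            (rmse(pred, gt), mae_euclidean(pred, gt), mae_axis(pred, gt, "z"), hausdorff(pred, gt))
        )
    arr = np.asarray(rows)
    if per_sample_csv is not None:
        np.savetxt(
            per_sample_csv, arr, delimiter=",",
            header="rmse_mm,mae_mm,mae_z_mm,hd_mm", comments="",
        )
    m = arr.mean(axis=0)
    return MetricsReport(float(m[0]), float(m[1]), float(m[2]), float(m[3]), len(rows))
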