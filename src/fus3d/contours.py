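"""Closed planar contours and polygon geometry helpers.

Contours are ordered ``(x, y)`` vertex lists in pixel coordinates
(sub-pixel precision, ``x`` = column, ``y`` = row).  The closing edge
from the last to the first vertex is implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.draw import polygon2mask


@dataclass(frozen=True)
class Contour:
    """A simple closed polygon, e.g. the extracted zero level set of one frame."""

    points: np.ndarray  # (N, 2) float, (x, y) px
    frame_index: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be (N, 2)")
        if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("contour needs at least 3 distinct vertices")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def is_simple(self) -> bool:
        return Polygon(self.points).is_valid

    def scaled(self, factor: float, about: np.ndarray | None = None) -> "Contour":
        """Contour scaled about a point (defaults to its own centroid)."""
        c = self.centroid if about is None else np.asarray(about, float)
        return Contour(c + factor * (self.points - c), self.frame_index)


def circle_contour(center, radius: float, n: int = 128, frame_index: int = 0) -> Contour:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    cx, cy = center
    return Contour(np.column_stack([cx + radius * np.cos(th), cy + radius * np.sin(th)]),
                   frame_index)


def resample_closed(points: np.ndarray, n: int = 256) -> np.ndarray:
    """Arc-length uniform resampling of a closed polygon to ``n`` points."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def polygon_signed_distance(shape: tuple[int, int], polygon: np.ndarray,
                            sample_step: float = 0.1) -> np.ndarray:
    """Signed Euclidean distance (px) from pixel centers to a polygon boundary.

    Negative inside, positive outside.  The boundary is resampled at
    ``sample_step`` px, so distances are exact to O(sample_step²/8)
    ≈ 1e-3 px at the default.  ``shape`` is (rows, cols).
    """
    from scipy.spatial import cKDTree

    poly = np.asarray(polygon, dtype=float)
    closed = np.vstack([poly, poly[:1]])
    perimeter = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
    n = max(int(np.ceil(perimeter / sample_step)), 3 * len(poly))
    dense = resample_closed(poly, n)

    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    p = np.column_stack([xs.ravel(), ys.ravel()])
    dmin = cKDTree(dense).query(p, k=1)[0]
    inside = shapely.contains_xy(Polygon(poly), p[:, 0], p[:, 1])
    sd = np.where(inside, -dmin, dmin)
    return sd.reshape(h, w)


def polygon_to_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Filled binary mask of the polygon interior; ``shape`` is (rows, cols)."""
    poly = np.asarray(polygon, dtype=float)
    return polygon2mask(shape, poly[:, ::-1])  # polygon2mask takes (row, col)
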