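"""3D reconstruction from segmented, pose-tagged 2D planes.

Pipeline: segmented masks → wall-surface rings (mask minus its erosion)
→ 3D wall point sets via the frame poses → splatted, Gaussian-smoothed
Cartesian intensity volumes for registration → averaged fusion across
views → object volume via interpolated signed-distance occupancy.

The volume estimator builds a per-plane 2D signed-distance field to
each contour (negative inside), maps the plane samples into the
reference frame (applying each view's registration transform), then
interpolates a 3D signed-distance field on a Cartesian grid by
normalized inverse-distance weighting of the k nearest plane samples;
voxels with interpolated SDF < 0 are counted as interior.  For a
parallel plane stack this reduces to a Cavalieri sum; it degrades
gracefully for sparse, non-parallel multi-view geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import disk

from .contours import Contour, polygon_signed_distance
from .errors import ReconstructionError
from .phantom import ImageFrame
from .transforms import RigidTransform

MAX_GRID_VOXELS = 512 ** 3


@dataclass(frozen=True)
class WallSurfaceSet:
    """3D wall-surface voxel coordinates (mm) from one view."""

    points: np.ndarray              # (N, 3) mm
    source_view: str = ""
    values: np.ndarray | None = None  # optional per-point intensities

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite wall points")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def transformed(self, t: RigidTransform) -> "WallSurfaceSet":
        return WallSurfaceSet(t.apply(self.points), self.source_view, self.values)


@dataclass
class VolumeGrid:
    """Scalar field on a regular Cartesian grid; values indexed [ix, iy, iz]."""

    values: np.ndarray
    origin: np.ndarray              # mm, position of voxel (0,0,0) center
    spacing: float                  # mm/voxel, isotropic
    occupancy: np.ndarray | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.origin) / self.spacing

    def voxel_centers(self) -> np.ndarray:
        idx = np.indices(self.values.shape).reshape(3, -1).T
        return idx * self.spacing + self.origin

    def sample(self, pts: np.ndarray, cval: float = 0.0) -> np.ndarray:
        """Trilinear interpolation at world points; ``cval`` outside."""
        coords = self.world_to_voxel(pts).T
        return ndimage.map_coordinates(self.values, coords, order=1, mode="constant", cval=cval)

    def in_bounds(self, pts: np.ndarray) -> np.ndarray:
        c = self.world_to_voxel(pts)
        shape = np.array(self.values.shape)
        return np.all((c >= 0) & (c <= shape - 1), axis=1)


# ---------------------------------------------------------------------------


def extract_wall_mask(seg_mask: np.ndarray, erosion_radius: int) -> np.ndarray:
    """Boundary-wall ring: mask minus its erosion by a disk of given radius."""
    mask = np.asarray(seg_mask).astype(bool)
    if erosion_radius < 0:
        raise ValueError("erosion radius must be >= 0")
    if erosion_radius == 0:
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(mask, structure=disk(erosion_radius))
    if not eroded.any():
        raise ReconstructionError(
            f"erosion radius {erosion_radius} annihilates the segmented region (target too small)")
    return mask & ~eroded


def planes_to_points(contour_masks, source_view: str = "") -> WallSurfaceSet:
    """Map every on-pixel of each (frame, mask) pair to world mm via its pose."""
    pts = []
    for frame, mask in contour_masks:
        if frame.pose is None:
            raise ReconstructionError(f"frame {frame.frame_index} is missing a pose")
        ys, xs = np.nonzero(np.asarray(mask))
        if len(xs) == 0:
            continue
        pts.append(frame.pixel_to_world(np.column_stack([xs, ys])))
    if not pts:
        raise ReconstructionError("no wall pixels in any plane")
    return WallSurfaceSet(np.vstack(pts), source_view)


def rasterize_to_grid(points: WallSurfaceSet, spacing: float,
                      smooth_sigma: float = 1.0, pad_voxels: int = 5) -> VolumeGrid:
    """Splat wall points to voxel counts, optionally Gaussian-smoothed.

    Smoothing turns the binary wall shell into a continuous intensity
    field with a usable gradient landscape for registration.
    """
    if points.n_points == 0:
        raise ReconstructionError("empty point set")
    lo = points.points.min(axis=0) - pad_voxels * spacing
    hi = points.points.max(axis=0) + pad_voxels * spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(shape)) > MAX_GRID_VOXELS:
        raise ReconstructionError(f"grid {tuple(shape)} exceeds the memory guard")
    idx = np.floor((points.points - lo) / spacing + 0.5).astype(int)
    idx = np.clip(idx, 0, shape - 1)
    values = np.zeros(shape, dtype=float)
    np.add.at(values, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    if smooth_sigma > 0:
        values = ndimage.gaussian_filter(values, smooth_sigma)
    return VolumeGrid(values=values, origin=lo, spacing=spacing)


def fuse_views(volumes: list[VolumeGrid], transforms: list[RigidTransform]) -> VolumeGrid:
    """Resample all volumes into the first one's grid and average.

    ``transforms[i]`` maps volume i's coordinates into the reference
    frame; the first transform is normally the identity.  Averaging the
    per-view intensities attenuates view-dependent artifacts and noise.
    """
    if not volumes:
        raise ValueError("no volumes to fuse")
    if len(volumes) != len(transforms):
        raise ValueError("need one transform per volume")
    ref = volumes[0]
    centers = ref.voxel_centers()
    total = np.zeros(len(centers))
    count = np.zeros(len(centers))
    for vol, t in zip(volumes, transforms):
        local = t.inverse().apply(centers)
        inb = vol.in_bounds(local)
        total[inb] += vol.sample(local[inb])
        count[inb] += 1
    fused = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return VolumeGrid(values=fused.reshape(ref.shape), origin=ref.origin.copy(),
                      spacing=ref.spacing, occupancy=(count.reshape(ref.shape) > 0))


def estimate_volume(planes, transforms=None, spacing: float = 0.5,
                    k_neighbors: int = 4, band_mm: float | None = None,
                    return_grid: bool = False):
    """Object volume (cc) from contoured planes via SDF-occupancy.

    ``planes``: sequence of (ImageFrame, Contour); ``transforms``: optional
    per-plane RigidTransform mapping that plane's view into the
    reference frame (None → identity, e.g. for the reference view).
    """
    planes = [p for p in planes if p[1] is not None]
    if len(planes) < 3:
        raise ReconstructionError("need at least 3 contoured planes")
    if transforms is None:
        transforms = [None] * len(planes)
    if len(transforms) != len(planes):
        raise ReconstructionError("need one transform per plane")
    if band_mm is None:
        band_mm = max(6.0 * spacing, 3.0)

    pts_all, sdf_all = [], []
    for (frame, contour), t in zip(planes, transforms):
        mm_per_px = float(np.mean(frame.pixel_spacing))
        sd = polygon_signed_distance(frame.shape, contour.points) * mm_per_px
        keep = sd < band_mm          # full interior + a band outside the boundary
        ys, xs = np.nonzero(keep)
        world = frame.pixel_to_world(np.column_stack([xs, ys]))
        if t is not None:
            world = t.apply(world)
        pts_all.append(world)
        sdf_all.append(sd[keep])
    pts = np.vstack(pts_all)
    sdf = np.concatenate(sdf_all)
    if sdf.min() >= 0:
        raise ReconstructionError("no interior samples: planes miss the object")

    interior = pts[sdf < 0]
    lo = interior.min(axis=0) - 3.0 * spacing
    hi = interior.max(axis=0) + 3.0 * spacing
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    if int(np.prod(shape)) > MAX_GRID_VOXELS:
        raise ReconstructionError(f"grid {tuple(shape)} exceeds the memory guard")
    grid = VolumeGrid(values=np.zeros(shape), origin=lo, spacing=spacing)
    centers = grid.voxel_centers()

    d, idx = cKDTree(pts).query(centers, k=k_neighbors)
    w = 1.0 / np.maximum(d, 1e-9)
    interp = (w * sdf[idx]).sum(axis=1) / w.sum(axis=1)
    occ = interp < 0
    grid.values = interp.reshape(grid.shape)
    grid.occupancy = occ.reshape(grid.shape)
    volume_cc = float(occ.sum()) * spacing ** 3 / 1000.0
    if return_grid:
        return volume_cc, grid
    return volume_cc
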