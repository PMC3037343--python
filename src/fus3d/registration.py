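"""Coarse-to-fine multi-view rigid registration.

Coarse: a 3D Hotelling (principal-axes) alignment of the two views'
wall-surface point sets — translate centroids together and align the
covariance eigenbases, enumerating the four right-handed eigenvector
sign combinations and keeping the candidate with the lowest overlap
mean-squared-error.  Fine: Levenberg–Marquardt minimization of

    f(P, T(Q)) = 1/n(T) · Σ [ I_R(p) − I_N(T(q)) ]²

over 6 rigid parameters (ZYX Euler angles about the moving centroid +
translation), where I_R is the reference view's smoothed wall-intensity
volume interpolated trilinearly at the transformed moving points and
I_N the moving view's own wall intensities (fixed per point).  The
coarse stage turns the global search into a local least-squares problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import RegistrationError
from .reconstruction import VolumeGrid, WallSurfaceSet, rasterize_to_grid
from .transforms import RigidTransform

MIN_OVERLAP_VOXELS = 100


@dataclass(frozen=True)
class HotellingFrame:
    """Principal-axes frame of a 3D point cloud."""

    centroid: np.ndarray            # (3,)
    axes: np.ndarray                # (3,3), columns = eigenvectors, descending eigenvalue
    eigenvalues: np.ndarray         # (3,), descending
    degenerate: bool = False        # near-isotropic or rank-deficient covariance


@dataclass
class RegistrationResult:
    transform: RigidTransform       # maps moving-view points into the reference frame
    objective: float                # final mean-squared error
    objective_init: float           # MSE at the coarse initialization
    n_overlap: int                  # moving points landing inside the reference grid
    coarse_transform: RigidTransform | None = None
    converged: bool = False
    n_lm_iters: int = 0
    objective_trace: list = field(default_factory=list)


def hotelling_frame(points: WallSurfaceSet) -> HotellingFrame:
    """Centroid and covariance eigenbasis (right-handed, descending λ)."""
    pts = points.points
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    if np.linalg.det(vec) < 0:
        vec[:, 2] = -vec[:, 2]
    # flag rank deficiency and (near-)equal eigenvalue pairs: either makes
    # one or more principal axes arbitrary, so sign enumeration must rely
    # on the objective to disambiguate
    degenerate = bool(lam[0] <= 0 or lam[2] / lam[0] < 1e-9
                      or (lam[0] - lam[1]) / lam[0] < 0.1
                      or (lam[1] - lam[2]) / lam[0] < 0.1)
    return HotellingFrame(centroid=centroid, axes=vec, eigenvalues=lam, degenerate=degenerate)


def _sign_candidates(ref: HotellingFrame, mov: HotellingFrame) -> list[RigidTransform]:
    """The four right-handed eigenvector sign disambiguations."""
    out = []
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = ref.axes @ np.diag(signs) @ mov.axes.T
        out.append(RigidTransform(R, ref.centroid - R @ mov.centroid))
    return out


def _objective(ref_volume: VolumeGrid, pts: np.ndarray, vals: np.ndarray) -> tuple[float, int]:
    """Overlap MSE and overlap count; out-of-grid points see intensity 0."""
    interp = ref_volume.sample(pts)
    n_in = int(ref_volume.in_bounds(pts).sum())
    return float(np.mean((interp - vals) ** 2)), n_in


def moving_intensities(moving: WallSurfaceSet, spacing: float,
                       smooth_sigma: float = 1.0) -> np.ndarray:
    """I_N at the moving points, from the view's own smoothed rasterization."""
    vol = rasterize_to_grid(moving, spacing, smooth_sigma)
    return vol.sample(moving.points)


def coarse_register(reference: WallSurfaceSet, moving: WallSurfaceSet,
                    ref_volume: VolumeGrid, mov_volume: VolumeGrid) -> RigidTransform:
    """Hotelling initialization: best of the four principal-axes alignments."""
    ref_hf = hotelling_frame(reference)
    mov_hf = hotelling_frame(moving)
    vals = mov_volume.sample(moving.points)
    best, best_score = None, np.inf
    for cand in _sign_candidates(ref_hf, mov_hf):
        score, n_in = _objective(ref_volume, cand.apply(moving.points), vals)
        if n_in == 0:
            continue
        if score < best_score:
            best, best_score = cand, score
    if best is None:
        raise RegistrationError("no principal-axes candidate overlaps the reference volume; "
                                "views do not satisfy the partial-overlap assumption")
    return best


def fine_register(ref_volume: VolumeGrid, moving_points: WallSurfaceSet,
                  init: RigidTransform, moving_values: np.ndarray | None = None,
                  max_iters: int = 60) -> RegistrationResult:
    """Levenberg–Marquardt refinement of the overlap-MSE objective."""
    q = moving_points.points
    if moving_values is None:
        moving_values = (moving_points.values if moving_points.values is not None
                         else moving_intensities(moving_points, ref_volume.spacing))
    vals = np.asarray(moving_values, dtype=float)
    q_init = init.apply(q)
    pivot = q_init.mean(axis=0)   # rotate about the moving centroid for conditioning

    trace: list[float] = []

    def transform_of(x: np.ndarray) -> RigidTransform:
        R = Rotation.from_euler("zyx", x[:3]).as_matrix()
        delta = RigidTransform(R, pivot - R @ pivot + x[3:])
        return delta.compose(init)

    def residuals(x: np.ndarray) -> np.ndarray:
        r = ref_volume.sample(transform_of(x).apply(q)) - vals
        trace.append(float(np.mean(r ** 2)))
        return r

    obj_init, n_in0 = _objective(ref_volume, q_init, vals)
    if n_in0 < MIN_OVERLAP_VOXELS:
        raise RegistrationError(f"initial overlap {n_in0} below the floor of {MIN_OVERLAP_VOXELS} voxels")

    # trilinear interpolation makes the residuals piecewise-smooth only, so
    # tight steptol would never trigger; bound the iteration count instead.
    res = least_squares(residuals, np.zeros(6), method="lm",
                        x_scale=[0.02, 0.02, 0.02, 1.0, 1.0, 1.0],
                        diff_step=1e-3, ftol=1e-9, xtol=1e-9, max_nfev=max_iters)
    if not np.isfinite(res.cost):
        raise RegistrationError("non-finite objective during LM refinement")
    transform = transform_of(res.x)
    objective, n_overlap = _objective(ref_volume, transform.apply(q), vals)
    if n_overlap < MIN_OVERLAP_VOXELS:
        raise RegistrationError(f"overlap shrank to {n_overlap} voxels during optimization")
    return RegistrationResult(transform=transform, objective=objective,
                              objective_init=obj_init, n_overlap=n_overlap,
                              coarse_transform=init, converged=bool(res.status > 0),
                              n_lm_iters=int(res.nfev), objective_trace=trace)


def _strided_subset(points: WallSurfaceSet, n_max: int) -> WallSurfaceSet:
    if points.n_points <= n_max:
        return points
    idx = np.linspace(0, points.n_points - 1, n_max).astype(int)
    vals = None if points.values is None else points.values[idx]
    return WallSurfaceSet(points.points[idx], points.source_view, vals)


def register_views(reference: WallSurfaceSet, moving: WallSurfaceSet,
                   spacing: float = 1.0, smooth_sigma: float = 1.0,
                   refine_spacing: float | None = None,
                   max_refine_points: int = 4000) -> RegistrationResult:
    """Full coarse-to-fine registration of one moving view to the reference.

    Hotelling initialization and an LM pass on volumes rasterized at
    ``spacing``, then a second LM pass at ``refine_spacing`` (default
    spacing/2) on a strided subsample of the moving points: the fine
    grid removes most of the voxel-binning bias of the coarse pass at a
    fraction of its cost.
    """
    ref_vol = rasterize_to_grid(reference, spacing, smooth_sigma)
    mov_vol = rasterize_to_grid(moving, spacing, smooth_sigma)
    init = coarse_register(reference, moving, ref_vol, mov_vol)
    vals = mov_vol.sample(moving.points)
    result = fine_register(ref_vol, moving, init, moving_values=vals)

    if refine_spacing is None:
        refine_spacing = spacing / 2.0
    if refine_spacing < spacing:
        ref_fine = rasterize_to_grid(reference, refine_spacing, smooth_sigma)
        sub = _strided_subset(moving, max_refine_points)
        mov_fine = rasterize_to_grid(moving, refine_spacing, smooth_sigma)
        sub_vals = mov_fine.sample(sub.points)
        refined = fine_register(ref_fine, sub, result.transform, moving_values=sub_vals)
        refined.coarse_transform = init
        refined.objective_trace = result.objective_trace + refined.objective_trace
        return refined
    return result
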