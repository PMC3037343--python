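"""Synthetic tracked-probe acquisitions of an ellipsoidal phantom.

Emulates multi-window freehand scanning of a calibrated egg/ellipsoid
phantom with known analytic volume: each generated frame is the exact
ellipsoid cross-section under that plane's 6-DOF pose, rendered with
Gaussian edge blur, an optional bright wall rim, angular weak-edge
arcs (boundary gaps), and correlated multiplicative Rayleigh speckle,
then quantized to 8 bits.  The calibration transform is the identity:
the pose IS the pixel-to-world map.

Pixel ``(px, py)`` of a frame maps to world mm as
``R @ (px*sx, py*sy, 0) + t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .contours import Contour
from .transforms import RigidTransform


@dataclass(frozen=True)
class PhantomSpec:
    """Ellipsoid phantom with analytic ground-truth volume (4/3)π·abc."""

    semi_axes: tuple[float, float, float] = (15.0, 10.0, 10.0)  # mm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)        # mm
    interior_intensity: float = 150.0
    background_intensity: float = 60.0
    wall_contrast: float = 0.0           # optional hyperechoic rim amplitude at the boundary
    wall_sigma: float = 0.8              # rim width, mm
    speckle_scale: float = math.sqrt(2.0 / math.pi)  # Rayleigh scale; this value → unit mean
    speckle_grain: float = 0.8           # correlation length of the speckle field, px
    edge_blur_sigma: float = 0.6         # mm
    gap_spec: tuple[tuple[float, float, float], ...] = ()
    """Weak-edge arcs: (center_deg, width_deg, attenuation in [0,1]); 0 = edge fully removed."""

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        for _, _, att in self.gap_spec:
            if not 0.0 <= att <= 1.0:
                raise ValueError("gap attenuation must be in [0, 1]")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def volume_cc(self) -> float:
        return self.volume_mm3 / 1000.0


@dataclass(frozen=True)
class SweepSpec:
    """One acquisition from one acoustic window.

    ``base_pose`` is the pose of the central frame.  Parallel sweeps
    translate along the image-plane normal (R·ez); fan sweeps rotate
    the plane about the image x-axis through the probe face (the
    world position of the top-center pixel of the central frame).
    """

    window_id: str = "top"
    sweep_type: str = "parallel"          # {"parallel", "fan"}
    n_frames: int = 41
    step: float = 0.75                    # mm (parallel) or degrees (fan)
    view_axis: str = "short-axis"
    pixel_spacing: tuple[float, float] = (0.5, 0.5)   # mm/px
    image_size: tuple[int, int] = (88, 88)            # (rows, cols)
    base_pose: RigidTransform = field(default_factory=RigidTransform.identity)
    inter_view_transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sweep_type not in ("parallel", "fan"):
            raise ValueError(f"unknown sweep_type {self.sweep_type!r}")
        if self.n_frames > 1 and self.step == 0:
            raise ValueError("degenerate sweep: zero step with more than one frame")

    def frame_poses(self) -> list[RigidTransform]:
        R0, t0 = self.base_pose.rotation, self.base_pose.translation
        offsets = (np.arange(self.n_frames) - (self.n_frames - 1) / 2.0) * self.step
        poses = []
        if self.sweep_type == "parallel":
            normal = R0 @ np.array([0.0, 0.0, 1.0])
            for d in offsets:
                poses.append(RigidTransform(R0, t0 + d * normal))
        else:  # fan: rotate about the image x-axis through the probe face
            h, w = self.image_size
            sx, _ = self.pixel_spacing
            pivot = self.base_pose.apply(np.array([(w - 1) / 2.0 * sx, 0.0, 0.0]))
            axis = R0 @ np.array([1.0, 0.0, 0.0])
            from scipy.spatial.transform import Rotation
            for d in offsets:
                rot = Rotation.from_rotvec(np.radians(d) * axis).as_matrix()
                poses.append(RigidTransform.rotation_about_point(rot, pivot).compose(self.base_pose))
        return poses


@dataclass(frozen=True)
class ImageFrame:
    """One 2D image with its probe pose — the atomic acquisition unit."""

    pixels: np.ndarray                    # (H, W) uint8
    pose: RigidTransform
    pixel_spacing: tuple[float, float]    # mm/px
    frame_index: int = 0
    truth_contour: Contour | None = None  # analytic cross-section, px, when the plane hits

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_to_world(self, pts_px: np.ndarray) -> np.ndarray:
        """Map (N,2) pixel coordinates to (N,3) world mm through the pose."""
        pts = np.asarray(pts_px, dtype=float)
        sx, sy = self.pixel_spacing
        p3 = np.column_stack([pts[:, 0] * sx, pts[:, 1] * sy, np.zeros(len(pts))])
        return self.pose.apply(p3)


# ---------------------------------------------------------------------------
# analytic plane / ellipsoid intersection


def _plane_ellipsoid_conic(spec: PhantomSpec, pose: RigidTransform,
                           pixel_spacing) -> tuple[np.ndarray, np.ndarray, float]:
    """Quadratic form of the cross-section ellipse in pixel coordinates.

    A pixel point x=(px,py) lies on the section boundary iff
    (M x + d)·(M x + d) = 1 with M, d below; returns (A, b, k) of the
    centered form (x-x0)ᵀ A (x-x0) = k after completing the square,
    where x0 = -A⁻¹ b.
    """
    a = np.asarray(spec.semi_axes, float)
    Dinv = np.diag(1.0 / a)
    sx, sy = pixel_spacing
    M = Dinv @ pose.rotation[:, :2] @ np.diag([sx, sy])
    d = Dinv @ (pose.translation - np.asarray(spec.center, float))
    A = M.T @ M
    b = M.T @ d
    c0 = float(d @ d - 1.0)
    k = float(b @ np.linalg.solve(A, b) - c0)
    return A, b, k


def analytic_cross_section(spec: PhantomSpec, pose: RigidTransform, pixel_spacing,
                           n_points: int = 256, frame_index: int = 0) -> Contour | None:
    """Exact intersection ellipse of the imaging plane with the phantom, in px.

    Returns None when the plane misses the ellipsoid.
    """
    A, b, k = _plane_ellipsoid_conic(spec, pose, pixel_spacing)
    if k <= 0:
        return None
    x0 = -np.linalg.solve(A, b)
    lam, Q = np.linalg.eigh(A)
    th = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    circ = np.column_stack([np.cos(th), np.sin(th)])
    pts = x0 + math.sqrt(k) * (circ / np.sqrt(lam)) @ Q.T
    return Contour(pts, frame_index)


def analytic_cross_section_area_mm2(spec: PhantomSpec, pose: RigidTransform, pixel_spacing) -> float:
    """Exact area (mm²) of the plane/ellipsoid section; 0 if the plane misses."""
    A, _, k = _plane_ellipsoid_conic(spec, pose, pixel_spacing)
    if k <= 0:
        return 0.0
    sx, sy = pixel_spacing
    return math.pi * k / math.sqrt(np.linalg.det(A)) * sx * sy


# ---------------------------------------------------------------------------
# rendering


def _render_frame(spec: PhantomSpec, pose: RigidTransform, sweep: SweepSpec,
                  rng: np.random.Generator, frame_index: int) -> ImageFrame:
    h, w = sweep.image_size
    sx, sy = sweep.pixel_spacing
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    plane = np.stack([xs * sx, ys * sy, np.zeros_like(xs)], axis=-1)
    world = plane @ pose.rotation.T + pose.translation
    rel = (world - np.asarray(spec.center)) / np.asarray(spec.semi_axes)
    inside = ((rel ** 2).sum(axis=-1) < 1.0).astype(float)

    truth = analytic_cross_section(spec, pose, sweep.pixel_spacing, frame_index=frame_index)

    sigma_px = spec.edge_blur_sigma / ((sx + sy) / 2.0)
    sharp = ndimage.gaussian_filter(inside, sigma_px, mode="nearest")
    delta = spec.interior_intensity - spec.background_intensity
    img = spec.background_intensity + delta * sharp

    if truth is not None:
        # wall rim + weak-edge arcs, applied around the analytic section
        from scipy.spatial import cKDTree
        cen = truth.centroid
        pix = np.column_stack([xs.ravel(), ys.ravel()])
        dist_px = cKDTree(truth.points).query(pix, k=1)[0].reshape(h, w)
        mean_spacing = (sx + sy) / 2.0
        rim = np.exp(-0.5 * (dist_px * mean_spacing / spec.wall_sigma) ** 2)

        weight = np.ones((h, w))
        if spec.gap_spec:
            ang = np.degrees(np.arctan2(ys - cen[1], xs - cen[0]))
            for cdeg, wdeg, att in spec.gap_spec:
                dang = (ang - cdeg + 180.0) % 360.0 - 180.0
                weight = np.where(np.abs(dang) <= wdeg / 2.0, att, weight)
            soft = ndimage.gaussian_filter(inside, 4.0 * sigma_px, mode="nearest")
            img = (spec.background_intensity
                   + delta * (weight * sharp + (1.0 - weight) * soft))
        img = img + spec.wall_contrast * weight * rim

    if spec.speckle_scale > 0:
        noise = rng.rayleigh(scale=spec.speckle_scale, size=(h, w))
        if spec.speckle_grain > 0:
            noise = ndimage.gaussian_filter(noise, spec.speckle_grain, mode="nearest")
        img = img * noise

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageFrame(pixels, pose, sweep.pixel_spacing, frame_index, truth)


def make_phantom_frames(spec: PhantomSpec, sweep: SweepSpec, seed: int) -> list[ImageFrame]:
    """Generate the sweep's frames; the seed fixes all randomness."""
    rng = np.random.default_rng(seed)
    return [_render_frame(spec, pose, sweep, rng, i)
            for i, pose in enumerate(sweep.frame_poses())]


def apply_inter_view_motion(frames: list[ImageFrame], motion: RigidTransform) -> list[ImageFrame]:
    """Left-compose every frame pose with a rigid subject motion; pixels unchanged.

    This is the unknown misalignment the registration stage must recover.
    """
    return [ImageFrame(f.pixels, motion.compose(f.pose), f.pixel_spacing,
                       f.frame_index, f.truth_contour) for f in frames]
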