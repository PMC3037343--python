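import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from fus3d.contours import circle_contour
from fus3d.errors import ReconstructionError
from fus3d.experiments import _plane_pose, exact_wall_points, standard_phantom, standard_views
from fus3d.phantom import ImageFrame, PhantomSpec, SweepSpec, apply_inter_view_motion, make_phantom_frames
from fus3d.reconstruction import (VolumeGrid, WallSurfaceSet, estimate_volume, extract_wall_mask,
                                  fuse_views, planes_to_points, rasterize_to_grid)
from fus3d.metrics import relative_volume_error
from fus3d.transforms import RigidTransform


def frame_with(pixels=None, pose=None, spacing=(0.5, 0.5), shape=(64, 64)):
    if pixels is None:
        pixels = np.zeros(shape, dtype=np.uint8)
    return ImageFrame(pixels, pose or RigidTransform.identity(), spacing)


class TestWallMask:
    def test_ring_pixel_count_matches_annulus(self):
        ys, xs = np.mgrid[:96, :96]
        d = np.hypot(xs - 48.0, ys - 48.0)
        mask = d < 24.0
        ring = extract_wall_mask(mask, 4)
        annulus = mask & (d >= 20.0)  # direct rasterization of the 4 px shell
        count, expected = ring.sum(), annulus.sum()
        assert abs(count - expected) / expected < 0.05
        assert not ring[48, 48]

    def test_zero_radius_gives_empty_difference(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        assert extract_wall_mask(mask, 0).sum() == 0

    def test_over_erosion_raises(self):
        mask = np.zeros((32, 32), bool)
        rr, cc = draw_disk((16, 16), 3)
        mask[rr, cc] = True
        with pytest.raises(ReconstructionError):
            extract_wall_mask(mask, 8)


class TestPlanesToPoints:
    def test_identity_pose_scales_by_spacing(self):
        mask = np.zeros((64, 64), bool)
        mask[20, 10] = True  # (row=20, col=10) -> (x=10, y=20) px
        pts = planes_to_points([(frame_with(), mask)])
        np.testing.assert_allclose(pts.points, [[5.0, 10.0, 0.0]])

    def test_translated_pose_offsets_points(self):
        mask = np.zeros((64, 64), bool)
        mask[20, 10] = True
        pose = RigidTransform(np.eye(3), (0.0, 0.0, 7.0))
        pts = planes_to_points([(frame_with(pose=pose), mask)])
        np.testing.assert_allclose(pts.points, [[5.0, 10.0, 7.0]])

    def test_sweep_points_lie_near_sphere_surface(self):
        spec = PhantomSpec(semi_axes=(10.0, 10.0, 10.0), speckle_scale=0.0)
        sweep = standard_views(15)[0]
        _, _, walls = exact_wall_points(spec, sweep, 0, erosion_radius=4)
        r = np.linalg.norm(walls.points, axis=1)
        margin = 4 * 0.5 + 0.5  # erosion depth (mm) + one voxel
        assert (r <= 10.0 + 0.5).all()
        assert (r >= 10.0 - margin - 0.5).all()


class TestRasterize:
    def test_single_point_single_voxel(self):
        vol = rasterize_to_grid(WallSurfaceSet(np.array([[1.0, 2.0, 3.0]])), 1.0, smooth_sigma=0)
        assert (vol.values > 0).sum() == 1

    def test_two_points_one_voxel_apart(self):
        pts = WallSurfaceSet(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
        vol = rasterize_to_grid(pts, 1.0, smooth_sigma=0)
        assert (vol.values == 1.0).sum() == 2

    def test_sphere_surface_centroid(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        vol = rasterize_to_grid(WallSurfaceSet(v * 10.0 + [3.0, -2.0, 5.0]), 0.5, smooth_sigma=0)
        idx = np.argwhere(vol.values > 0)
        centroid = (idx * vol.spacing + vol.origin).mean(axis=0)
        np.testing.assert_allclose(centroid, [3.0, -2.0, 5.0], atol=0.25)


class TestFuse:
    def make_vol(self, seed=0):
        rng = np.random.default_rng(seed)
        pts = WallSurfaceSet(rng.normal(size=(500, 3)) * 4)
        return rasterize_to_grid(pts, 1.0)

    def test_single_volume_identity(self):
        vol = self.make_vol()
        fused = fuse_views([vol], [RigidTransform.identity()])
        np.testing.assert_allclose(fused.values, vol.values, atol=1e-9)

    def test_mean_is_idempotent(self):
        vol = self.make_vol()
        fused = fuse_views([vol, vol], [RigidTransform.identity()] * 2)
        np.testing.assert_allclose(fused.values, vol.values, atol=1e-9)

    def test_two_half_coverages_union_support(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(6000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sphere = v * 8.0
        left = WallSurfaceSet(sphere[sphere[:, 0] < 1.0])
        right = WallSurfaceSet(sphere[sphere[:, 0] > -1.0])
        vol_l = rasterize_to_grid(left, 1.0)
        vol_r = rasterize_to_grid(right, 1.0)
        # resample everything on a common grid covering the full sphere
        full = rasterize_to_grid(WallSurfaceSet(sphere), 1.0)
        base = VolumeGrid(np.zeros(full.shape), full.origin, full.spacing)
        fused = fuse_views([base, vol_l, vol_r], [RigidTransform.identity()] * 3)
        sup_l = fuse_views([base, vol_l], [RigidTransform.identity()] * 2)
        sup_r = fuse_views([base, vol_r], [RigidTransform.identity()] * 2)
        assert (fused.values > 0).sum() > (sup_l.values > 0).sum()
        assert (fused.values > 0).sum() > (sup_r.values > 0).sum()


class TestEstimateVolume:
    def sphere_planes(self, n=41, step=0.75, seed=1):
        spec = PhantomSpec(semi_axes=(12.0, 12.0, 12.0), speckle_scale=0.0)
        pose = _plane_pose((0, 1, 0), (0, 0, 1), (0, 0, 0), (88, 88), (0.5, 0.5))
        sweep = SweepSpec(n_frames=n, step=step, base_pose=pose)
        frames = make_phantom_frames(spec, sweep, seed)
        return spec, [(f, f.truth_contour) for f in frames if f.truth_contour is not None]

    def test_sphere_parallel_stack_within_two_percent(self):
        spec, planes = self.sphere_planes()
        est = estimate_volume(planes, spacing=0.5)
        assert abs(relative_volume_error(est, spec.volume_cc)) < 2.0

    def test_two_orthogonal_views_within_three_percent(self):
        spec = PhantomSpec(semi_axes=(15.0, 10.0, 10.0), speckle_scale=0.0)
        sweeps = standard_views(20)
        f0, c0, _ = exact_wall_points(spec, sweeps[0], 1)
        f3, c3, _ = exact_wall_points(spec, sweeps[3], 2)
        planes = [(f, c) for f, c in zip(f0, c0) if c] + [(f, c) for f, c in zip(f3, c3) if c]
        est = estimate_volume(planes, spacing=0.5)
        assert abs(relative_volume_error(est, spec.volume_cc)) < 3.0

    def test_rigid_motion_invariance(self):
        spec, planes = self.sphere_planes()
        est = estimate_volume(planes, spacing=0.5)
        motion = RigidTransform.from_euler((25.0, 10.0, -5.0), (30.0, -12.0, 8.0))
        frames = apply_inter_view_motion([f for f, _ in planes], motion)
        moved = [(fm, c) for fm, (_, c) in zip(frames, planes)]
        est_m = estimate_volume(moved, spacing=0.5)
        # one voxel layer over the sphere surface bounds the allowed change
        shell_cc = 4 * np.pi * 12.0 ** 2 * 0.5 / 1000.0
        assert abs(est_m - est) < shell_cc

    def test_monotone_refinement_with_plane_count(self):
        spec, planes10 = self.sphere_planes(n=10, step=30.0 / 9)
        _, planes40 = self.sphere_planes(n=40, step=30.0 / 39)
        e10 = abs(relative_volume_error(estimate_volume(planes10, spacing=0.5), spec.volume_cc))
        e40 = abs(relative_volume_error(estimate_volume(planes40, spacing=0.5), spec.volume_cc))
        assert e40 <= e10

    def test_grid_refinement_is_stable(self):
        spec, planes = self.sphere_planes()
        coarse = estimate_volume(planes, spacing=1.0)
        fine = estimate_volume(planes, spacing=0.5)
        shell_cc = 4 * np.pi * 12.0 ** 2 * 1.0 / 1000.0
        assert abs(fine - coarse) < shell_cc

    def test_planes_missing_object_raise(self):
        frames = [frame_with(shape=(32, 32)) for _ in range(4)]
        with pytest.raises(ReconstructionError):
            estimate_volume([(f, None) for f in frames], spacing=0.5)

    def test_too_few_planes_raise(self):
        spec, planes = self.sphere_planes()
        with pytest.raises(ReconstructionError):
            estimate_volume(planes[:2], spacing=0.5)
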