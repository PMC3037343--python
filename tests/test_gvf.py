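import numpy as np
import pytest
from scipy import ndimage, optimize

from fus3d.errors import GvfDivergenceError
from fus3d.gvf import EdgeMaps, compute_edge_maps, compute_gvf, gvf_energy, normalize_field


def zero_edge(shape=(32, 32)):
    z = np.zeros(shape)
    return EdgeMaps(g=np.ones(shape), f=z, grad_g=np.stack([z, z]), sigma=1.0, alpha=1.0)


class TestEdgeMaps:
    def test_constant_image(self):
        em = compute_edge_maps(np.full((20, 30), 7.0), sigma=1.0, alpha=0.5)
        np.testing.assert_array_equal(em.f, 0.0)
        np.testing.assert_array_equal(em.g, 1.0)
        np.testing.assert_array_equal(em.grad_g, 0.0)

    def test_step_edge_lowers_g(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        em = compute_edge_maps(img, sigma=1.0, alpha=1.0)
        assert em.g[16, 16] < em.g[16, 2]
        assert em.g.min() > 0.0 and em.g.max() <= 1.0

    def test_f_scales_with_inverse_alpha_squared(self, disk_image):
        e1 = compute_edge_maps(disk_image, sigma=2.0, alpha=1.0)
        e2 = compute_edge_maps(disk_image, sigma=2.0, alpha=2.0)
        np.testing.assert_allclose(e2.f, e1.f / 4.0, rtol=1e-12, atol=1e-15)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            compute_edge_maps(np.zeros((4, 4, 4)), 1.0, 1.0)
        with pytest.raises(ValueError):
            compute_edge_maps(np.zeros((4, 4)), -1.0, 1.0)


class TestGvf:
    def test_zero_edge_map_gives_zero_field(self):
        field = compute_gvf(zero_edge(), mu=0.2, n_iter=50, dt=1.0)
        np.testing.assert_array_equal(field.u, 0.0)
        np.testing.assert_array_equal(field.v, 0.0)

    def test_zero_iterations_returns_initialization(self, disk_edge_map):
        field = compute_gvf(disk_edge_map, mu=0.2, n_iter=0, dt=1.0)
        dy, dx = np.gradient(disk_edge_map.f)
        np.testing.assert_array_equal(field.u, dx)
        np.testing.assert_array_equal(field.v, dy)

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            compute_gvf(zero_edge(), mu=0.5, n_iter=10, dt=1.0)  # bound is 0.5

    def test_energy_non_increasing(self, disk_edge_map):
        em = disk_edge_map
        f_unit = em.f / em.f.max()
        em_unit = EdgeMaps(em.g, f_unit, em.grad_g, em.sigma, em.alpha)
        dy, dx = np.gradient(f_unit)
        energies = []
        for n in (0, 5, 20, 60, 120):
            fl = compute_gvf(em_unit, mu=0.2, n_iter=n, dt=1.0)
            energies.append(gvf_energy(fl.u, fl.v, dx, dy, 0.2))
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))

    def test_disk_field_points_inward_and_matches_energy_descent_oracle(self):
        """On the axis outside a bright disk edge map, u points toward the center.

        Cross-checked against an independent minimizer (L-BFGS on the
        same discretized energy) on a 32x32 grid.
        """
        ys, xs = np.mgrid[:32, :32]
        f = np.exp(-(((xs - 16.0) ** 2 + (ys - 16.0) ** 2) ** 0.5 - 8.0) ** 2 / 4.0)
        em = EdgeMaps(g=1 / (1 + f), f=f, grad_g=np.stack(np.gradient(1 / (1 + f))[::-1]),
                      sigma=1.0, alpha=1.0)
        field = compute_gvf(em, mu=0.2, n_iter=300, dt=1.0)

        dy, dx = np.gradient(f)
        b = dx ** 2 + dy ** 2

        def energy(z):
            u, v = z[:1024].reshape(32, 32), z[1024:].reshape(32, 32)
            return gvf_energy(u, v, dx, dy, 0.2)

        z0 = np.concatenate([dx.ravel(), dy.ravel()])
        res = optimize.minimize(energy, z0, method="L-BFGS-B",
                                options={"maxiter": 300})
        u_oracle = res.x[:1024].reshape(32, 32)

        # points on the horizontal axis right of the disk: inward means u < 0
        for x in (27, 29, 31):
            assert field.u[16, x] < 0
            assert u_oracle[16, x] < 0

    def test_mirrored_edge_map_mirrors_field(self, disk_edge_map):
        em = disk_edge_map
        em_m = EdgeMaps(em.g[:, ::-1], em.f[:, ::-1], em.grad_g, em.sigma, em.alpha)
        a = compute_gvf(em, mu=0.2, n_iter=40, dt=1.0)
        m = compute_gvf(em_m, mu=0.2, n_iter=40, dt=1.0)
        np.testing.assert_allclose(m.u, -a.u[:, ::-1], atol=1e-10)
        np.testing.assert_allclose(m.v, a.v[:, ::-1], atol=1e-10)

    def test_capture_range_extends_beyond_gradient_support(self):
        """Normalized GVF stays inward-pointing well outside the edge's support."""
        ys, xs = np.mgrid[:96, :96]
        r = np.hypot(xs - 48.0, ys - 48.0)
        sigma = 2.0
        f = np.exp(-(r - 15.0) ** 2 / (2 * sigma ** 2))
        em = EdgeMaps(g=1 / (1 + f), f=f, grad_g=np.stack(np.gradient(1 / (1 + f))[::-1]),
                      sigma=sigma, alpha=1.0)
        field = compute_gvf(em, mu=0.2, n_iter=400, dt=1.0)
        un, vn = normalize_field(field.u, field.v)
        # sample a ring 3 sigma beyond the gradient support (r = 15 + 3σ + 3σ)
        probe_r = 15.0 + 6 * sigma
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        px = (48 + probe_r * np.cos(th)).astype(int)
        py = (48 + probe_r * np.sin(th)).astype(int)
        inward = -np.stack([np.cos(th), np.sin(th)])
        dots = un[py, px] * inward[0] + vn[py, px] * inward[1]
        assert (dots > 0).all()  # angle to inward radial direction < 90 degrees

    def test_divergence_reports_iteration(self):
        ys, xs = np.mgrid[:16, :16]
        f = 1e6 * np.exp(-((xs - 8.0) ** 2 + (ys - 8.0) ** 2) / 8.0)
        em = EdgeMaps(g=1 / (1 + f), f=f, grad_g=np.stack(np.gradient(1 / (1 + f))[::-1]),
                      sigma=1.0, alpha=1.0)
        with pytest.raises(GvfDivergenceError):
            compute_gvf(em, mu=0.2, n_iter=200, dt=1.0)
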