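import numpy as np
import pytest
from scipy import ndimage

from fus3d.contours import Contour, circle_contour


@pytest.fixture(scope="session")
def disk_image():
    """Clean 128x128 disk (r=30 px) with a soft edge: interior 150, background 60."""
    h = w = 128
    ys, xs = np.mgrid[:h, :w]
    inside = ((xs - 64.0) ** 2 + (ys - 64.0) ** 2 < 30.0 ** 2).astype(float)
    img = 60.0 + 90.0 * ndimage.gaussian_filter(inside, 1.2)
    return img


@pytest.fixture(scope="session")
def disk_truth():
    return circle_contour((64.0, 64.0), 30.0, n=256)


@pytest.fixture(scope="session")
def pentagon_seed():
    """Small off-center pentagon well inside the disk, far from its boundary."""
    th = np.linspace(0, 2 * np.pi, 5, endpoint=False) + 0.4
    pts = np.column_stack([60.0 + 9.0 * np.cos(th), 67.0 + 9.0 * np.sin(th)])
    return Contour(pts)


@pytest.fixture(scope="session")
def disk_edge_map():
    """Edge map of the clean disk at sigma=2, alpha=2 (shared by GVF tests)."""
    from fus3d.gvf import compute_edge_maps
    h = w = 64
    ys, xs = np.mgrid[:h, :w]
    inside = ((xs - 32.0) ** 2 + (ys - 32.0) ** 2 < 14.0 ** 2).astype(float)
    img = 60.0 + 90.0 * ndimage.gaussian_filter(inside, 1.2)
    return compute_edge_maps(img, sigma=2.0, alpha=2.0)
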