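import numpy as np
import pytest

from cdltools import geometry as geo
from cdltools import synthetic as syn


@pytest.fixture(scope="session")
def default_spiral():
    """Default synthetic cochlea (curve + integration ground truth)."""
    return syn.make_spiral()


@pytest.fixture(scope="session")
def clean_aligned(default_spiral):
    """Noiseless 500-point cloud of the default spiral, aligned."""
    curve, _ = default_spiral
    cloud = syn.sample_point_cloud(curve, n=500, noise_sd=0.0, seed=1)
    return geo.align_to_modiolar_frame(cloud)


@pytest.fixture(scope="session")
def clean_spline(clean_aligned):
    return geo.fit_lateral_wall_spline(clean_aligned)


def circle_cloud(radius=4.5, span_deg=355.0, n=200, z=0.0):
    """Planar circle arc starting at (radius, 0), counter-clockwise."""
    theta = np.radians(np.linspace(0.0, span_deg, n))
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                           np.full(n, z)])
    return geo.LateralWallPointCloud(pts, rw_index=0, side="right")


def circle_curve(radius=3.0, span_deg=355.0, n=400):
    """SplineCurve on a planar circle (canonical pose)."""
    cloud = circle_cloud(radius=radius, span_deg=span_deg, n=n)
    aligned = geo.AlignedCochlea(cloud=cloud)
    return geo.fit_lateral_wall_spline(aligned)


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return geo.RigidTransform(Q, rng.normal(scale=5.0, size=3))
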