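import numpy as np
import pytest
from shapely.geometry import box

from phenomass import fieldsim as fs
from phenomass.lidar_metrics import PointCloud


@pytest.fixture(scope="session")
def default_layout():
    return fs.generate_layout(fs.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def one_plot_truth():
    """One vegetative-stage plot: three rows, no reproductive spikes."""
    cfg = fs.SimulationConfig(seed=7, n_plots=1, plots_per_column=1,
                              season="late_spring", reproductive_fraction=0.0)
    layout = fs.generate_layout(cfg)
    return layout, fs.simulate_canopies(layout, cfg)


def cloud_from_surface(surface, bounds, spacing=0.005):
    """Dense point cloud sampling a callable surface(x, y) on a grid."""
    x0, y0, x1, y1 = bounds
    xs = np.arange(x0 + spacing / 2, x1, spacing)
    ys = np.arange(y0 + spacing / 2, y1, spacing)
    gx, gy = np.meshgrid(xs, ys)
    z = surface(gx, gy)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.asarray(z).ravel()])
    return PointCloud(points=pts, frame_index=np.zeros(len(pts), dtype=int))


def slab_surface(height, footprint):
    """Piecewise-constant canopy: `height` inside the footprint box, else 0."""
    fx0, fy0, fx1, fy1 = footprint

    def surface(x, y):
        inside = (x >= fx0) & (x < fx1) & (y >= fy0) & (y < fy1)
        return np.where(inside, height, 0.0)

    return surface


@pytest.fixture()
def slab_cloud():
    """Dense cloud over a 1.0 x 0.25 m slab of height 0.45 m inside a 1.2 x 0.45 m zone."""
    footprint = (0.1, 0.1, 1.1, 0.35)
    surf = slab_surface(0.45, footprint)
    cloud = cloud_from_surface(surf, (0.0, 0.0, 1.2, 0.45), spacing=0.005)
    polygon = box(0.0, 0.0, 1.2, 0.45)
    return cloud, polygon, footprint


def random_regression_data(seed, n=100, k=5, beta=None, noise=1.0):
    """Random design + linear response for model-fitting oracles."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    names = [f"x{i + 1}" for i in range(k)]
    if beta is None:
        beta = rng.normal(size=k)
    y = 2.0 + X @ beta + rng.normal(0.0, noise, size=n)
    df = pd.DataFrame(X, columns=names)
    df["FM"] = y
    return df, names
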