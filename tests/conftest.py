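import numpy as np
import pytest

from tractoshape.geometry import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_clouds(rng):
    """Twelve random non-degenerate 21-point clouds (smooth random walks)."""
    clouds = []
    for i in range(12):
        steps = rng.normal(0.0, 2.0, size=(20, 3))
        pts = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
        clouds.append(PointCloud(pts, source_id=f"rw{i}"))
    return clouds


@pytest.fixture
def line_distance_matrix():
    """Exact distances of 10 points on a line (a flat 1-D manifold)."""
    from tractoshape.shape_distance import DistanceMatrix

    x = np.array([0.0, 1.0, 2.5, 3.0, 4.5, 6.0, 6.5, 8.0, 9.0, 11.0])
    D = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(D, tuple(f"p{i}" for i in range(10))), x
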