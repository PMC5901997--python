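import numpy as np
import pytest

from epidiatom.tables import AbundanceTable, DistanceMatrix


@pytest.fixture
def small_count_table() -> AbundanceTable:
    return AbundanceTable(
        ["s1", "s2", "s3"],
        ["taxA", "taxB", "taxC"],
        np.array([[10.0, 30.0, 60.0], [5.0, 5.0, 0.0], [0.0, 20.0, 20.0]]),
        "count",
    )


def points_to_distance_matrix(points: np.ndarray, labels=None) -> DistanceMatrix:
    """Euclidean distances of a point cloud as a DistanceMatrix."""
    from scipy.spatial.distance import pdist, squareform

    n = len(points)
    labels = labels or [f"p{i}" for i in range(n)]
    return DistanceMatrix(labels, squareform(pdist(points)))


@pytest.fixture
def planar_points_dm() -> DistanceMatrix:
    rng = np.random.default_rng(42)
    return points_to_distance_matrix(rng.normal(size=(5, 2)))
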