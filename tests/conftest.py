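import numpy as np
import pytest

from smoothkit import SpotCoordinates, build_knn_graph, build_prior


def square_grid_coords(rows: int, cols: int) -> SpotCoordinates:
    ids = [f"s{i}" for i in range(rows * cols)]
    xy = [[i % cols, i // cols] for i in range(rows * cols)]
    return SpotCoordinates(ids, xy, "square")


def hex_lattice_coords(rows: int, cols: int) -> SpotCoordinates:
    """Regular triangular ('hex-packed') lattice: interior spots have 6
    equidistant nearest neighbors."""
    pts, ids = [], []
    for r in range(rows):
        for c in range(cols):
            pts.append([c + 0.5 * (r % 2), r * np.sqrt(3) / 2])
            ids.append(f"h{r}_{c}")
    return SpotCoordinates(ids, pts, "hex")


@pytest.fixture(scope="session")
def grid10():
    return square_grid_coords(10, 10)


@pytest.fixture(scope="session")
def graph10(grid10):
    return build_knn_graph(grid10, 4)


@pytest.fixture(scope="session")
def prior10(graph10):
    return build_prior(graph10, "ICAR", 0.99)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
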