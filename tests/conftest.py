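import numpy as np
import pytest

from implant_access import build_paper_fixture, classify_all
from implant_access.rasters import Raster


@pytest.fixture(scope="session")
def fixture_records():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_readiness(fixture_records):
    return classify_all(fixture_records)


@pytest.fixture
def uniform_surface():
    """21x21 uniform 2.5 kph walking surface, 100 m cells."""
    return Raster(np.full((21, 21), 2.5), cell_size=100.0)


def materialized_dijkstra(data: np.ndarray, cell_size: float, sources):
    """Independent oracle: explicit sparse graph + scipy Dijkstra.

    ``data`` holds per-cell speeds in kph (NaN impassable); ``sources`` are
    (row, col) cells. Returns minutes per cell, NaN where unreachable or
    impassable.
    """
    import math

    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra

    n_rows, n_cols = data.shape
    t = 60.0 / (data * 1000.0)  # minutes per meter
    graph = lil_matrix((n_rows * n_cols, n_rows * n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            if np.isnan(t[r, c]):
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    nr, nc = r + dr, c + dc
                    if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                        continue
                    if np.isnan(t[nr, nc]):
                        continue
                    d = cell_size * (math.sqrt(2) if dr and dc else 1.0)
                    graph[r * n_cols + c, nr * n_cols + nc] = (
                        d * (t[r, c] + t[nr, nc]) / 2.0
                    )
    idx = [r * n_cols + c for r, c in sources]
    dist = dijkstra(graph.tocsr(), indices=idx).min(axis=0).reshape(n_rows, n_cols)
    dist = np.where(np.isinf(dist), np.nan, dist)
    dist[np.isnan(data)] = np.nan
    return dist
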