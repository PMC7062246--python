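import numpy as np
import pytest

from habrisk import background as bg
from habrisk.fixture_io import default_correlation
from habrisk.predictors import extract_design_table
from habrisk.raster import RasterGrid, RasterStack
from habrisk.synthetic_fixtures import (
    generate_landscape,
    make_virtual_species,
    sample_presences,
)


@pytest.fixture(scope="session")
def landscape() -> RasterStack:
    """Shared 64x64, 4-layer correlated landscape."""
    return generate_landscape(
        4, (64, 64), spatial_range=4.0, inter_var_correlation=default_correlation(4),
        seed=101,
    )


@pytest.fixture(scope="session")
def species(landscape):
    return make_virtual_species(landscape, {"x1": 3.0, "x2": -3.0}, intercept=-6.0)


@pytest.fixture(scope="session")
def presences(species):
    return sample_presences(species, 200, seed=202)


@pytest.fixture(scope="session")
def kde_background(landscape, presences):
    kde = bg.fit_kde(presences.xy)
    extent = bg.buffered_mcp(presences.xy)
    return bg.sample_kde_background(
        kde, extent, n=1000, seed=303, template=landscape.template
    )


@pytest.fixture(scope="session")
def design_table(landscape, presences, kde_background):
    return extract_design_table(landscape, presences, kde_background)


@pytest.fixture
def toy_grid() -> RasterGrid:
    """3x3 grid, origin (0, 0), 10-unit cells, values 1..9 row-major
    from the top-left."""
    return RasterGrid(
        np.arange(1.0, 10.0).reshape(3, 3), x0=0.0, y0=0.0, cell_size=10.0
    )


def separable_table():
    """Linearly separable toy: presences at x1 > 0.8, background < 0.2."""
    import pandas as pd

    from habrisk.predictors import DesignTable

    rng = np.random.default_rng(7)
    n = 30
    x_pres = rng.uniform(0.8, 1.0, n)
    x_back = rng.uniform(0.0, 0.2, n)
    x2 = rng.normal(size=2 * n)
    frame = pd.DataFrame(
        {
            "point_id": np.arange(2 * n),
            "x": np.concatenate([x_pres, x_back]) * 100,
            "y": rng.uniform(0, 100, 2 * n),
            "response": np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)],
            "x1": np.concatenate([x_pres, x_back]),
            "x2": x2,
        }
    )
    return DesignTable(frame, ["x1", "x2"])


@pytest.fixture
def separable_design_table():
    return separable_table()
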