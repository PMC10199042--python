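"""Shared fixtures: small rasters and a compact synthetic landscape.

Fixture problem sizes are scaled down from the full study design (smaller
extents, fewer clusters, reduced cluster separation where the extent
demands it) while keeping the structural parameters — 150 m within-cluster
spacing, square 4-plot templates, 30 m cells — intact.
"""

from __future__ import annotations

import numpy as np
import pytest

from socmap.raster import GridTransform, Raster
from socmap.synth import NoiseParams, make_landscape

CRS = "EPSG:32644"


def make_raster(values, cell_size=30.0, nodata=-9999.0, x0=500_000.0, y0=3_200_000.0):
    return Raster(
        values=np.asarray(values, dtype=float),
        transform=GridTransform(x0, y0, cell_size),
        crs_id=CRS,
        nodata=nodata,
    )


@pytest.fixture
def flat_dem():
    return make_raster(np.full((8, 8), 500.0))


@pytest.fixture(scope="session")
def landscape_small():
    """96x96-cell landscape, 6 clusters (separation scaled to the extent)."""
    return make_landscape(
        n_rows=96,
        n_cols=96,
        n_clusters=6,
        min_cluster_sep_m=700.0,
        noise=NoiseParams(partial_sill=150.0, range_m=1200.0, nugget=64.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def landscape_plots(landscape_small):
    from socmap.plots import extract_at_plots

    design = extract_at_plots(landscape_small.stack, landscape_small.plots)
    assert not design["missing"].any()
    return landscape_small.plots, design[landscape_small.stack.names]
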