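"""Aggregation to coarser grids and comparison against reference SOC maps.

The fine prediction (30 m) is block-averaged to the resolution of a
reference product (~250 m or ~1 km, i.e. integer factors of the fine grid),
then compared cell by cell: pooled RMSE and mean bias, plus RMSE within
elevation zones (by default < 1000, 1000-3000 and > 3000 m a.s.l., the
conventional Himalayan foothill / mid-mountain / high-mountain bands).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import rmse as _rmse
from .raster import GridTransform, Raster, RasterError

__all__ = ["ComparisonResult", "aggregate_to_grid", "compare_maps", "DEFAULT_ZONE_EDGES"]

DEFAULT_ZONE_EDGES = (1000.0, 3000.0)


@dataclass
class ComparisonResult:
    pairs: pd.DataFrame  # predicted, reference, (elevation, zone) per coarse cell
    rmse: float
    bias: float  # mean(reference - predicted)
    zone_rmse: dict[str, float]
    zone_counts: dict[str, int]


def aggregate_to_grid(fine: Raster, factor: int) -> tuple[Raster, Raster]:
    """Block mean to a grid ``factor`` times coarser.

    Each coarse cell is the mean of its valid fine cells (partial edge
    blocks use the cells available); a coarse cell with no valid fine cell
    is nodata. Returns (coarse raster, fraction-of-valid-fine-cells raster).
    """
    if int(factor) != factor or factor < 1:
        raise RasterError(f"aggregation factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    nr, nc = fine.shape
    if factor > min(nr, nc):
        raise RasterError(f"factor {factor} exceeds grid dimensions {fine.shape}")
    out_r, out_c = -(-nr // factor), -(-nc // factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = fine.nan_values()
    blocks = padded.reshape(out_r, factor, out_c, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(out_r, out_c, factor * factor)
    count = np.isfinite(blocks).sum(axis=2)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(blocks, axis=2) / count
    mean[count == 0] = np.nan
    frac = count / float(factor * factor)
    t = fine.transform
    coarse_transform = GridTransform(t.x_origin, t.y_origin, t.cell_size * factor)
    coarse = Raster(mean, coarse_transform, fine.crs_id, nodata=fine.nodata)
    frac_r = Raster(frac, coarse_transform, fine.crs_id, nodata=-1.0)
    return coarse, frac_r


def _zone_label(elev: float, edges: tuple[float, ...]) -> str:
    if elev <= edges[0]:
        return f"<{edges[0]:g}"
    for lo, hi in zip(edges, edges[1:]):
        if elev <= hi:
            return f"{lo:g}-{hi:g}"
    return f">{edges[-1]:g}"


def compare_maps(
    predicted: Raster,
    reference: Raster,
    dem: Raster | None = None,
    zone_edges: tuple[float, ...] = DEFAULT_ZONE_EDGES,
) -> ComparisonResult:
    """Cell-wise comparison of two aligned coarse maps.

    Pairs are formed only where both maps are valid. Bias is
    mean(reference - predicted). With a DEM, per-zone RMSE uses elevation
    bands defined by ``zone_edges``; pair-count-weighted squared errors of
    the zones pool back to the overall RMSE.
    """
    if not predicted.same_grid(reference):
        raise RasterError("predicted and reference maps are on different grids")
    if dem is not None and not predicted.same_grid(dem):
        raise RasterError("DEM is not aligned with the comparison grids")
    p = predicted.nan_values()
    r = reference.nan_values()
    valid = np.isfinite(p) & np.isfinite(r)
    if dem is not None:
        valid &= np.isfinite(dem.nan_values())
    if not valid.any():
        raise RasterError("no overlapping valid cells to compare")
    pairs = pd.DataFrame({"predicted": p[valid], "reference": r[valid]})
    overall = _rmse(pairs["reference"], pairs["predicted"])
    bias = float(np.mean(pairs["reference"] - pairs["predicted"]))
    zone_rmse: dict[str, float] = {}
    zone_counts: dict[str, int] = {}
    if dem is not None:
        elev = dem.nan_values()[valid]
        pairs["elevation"] = elev
        pairs["zone"] = [_zone_label(e, zone_edges) for e in elev]
        for zone, grp in pairs.groupby("zone"):
            zone_rmse[zone] = _rmse(grp["reference"], grp["predicted"])
            zone_counts[zone] = len(grp)
    return ComparisonResult(
        pairs=pairs, rmse=overall, bias=bias,
        zone_rmse=zone_rmse, zone_counts=zone_counts,
    )
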