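"""Terrain and accessibility covariates derived from a DEM and masks.

Implements the predictor layers that a digital-soil-mapping stack derives
from elevation: slope (Horn stencil, degrees), topographic position index
(TPI), topographic wetness index (TWI, D8 routing after priority-flood sink
filling), a horizon-based wind-exposure index (dimensionless; 1 on flat
terrain, > 1 exposed, < 1 sheltered), Euclidean distance from the forest
edge, and a least-cost walking-time surface from a road network
(Naismith-style flat/uphill/downhill pace terms on the 8-connected grid).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .raster import Raster, RasterError

__all__ = [
    "slope",
    "tpi",
    "twi",
    "wind_exposure",
    "distance_from_edge",
    "cost_surface",
    "fill_sinks",
    "d8_flow",
    "FlowField",
    "WalkParams",
]

# 8-neighbour offsets, fixed order for deterministic tie-breaks
_D8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _require_dem(dem: Raster, min_dim: int = 3) -> None:
    nr, nc = dem.shape
    if nr < min_dim or nc < min_dim:
        raise RasterError(f"DEM must be at least {min_dim}x{min_dim}, got {dem.shape}")


# ---------------------------------------------------------------------------
# Slope (Horn 3x3) and TPI
# ---------------------------------------------------------------------------

def _horn_gradients(z: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
    dzdx = ndimage.correlate(z, kx, mode="nearest") / (8.0 * cell_size)
    dzdy = ndimage.correlate(z, ky, mode="nearest") / (8.0 * cell_size)
    return dzdx, dzdy


def slope(dem: Raster) -> Raster:
    """Slope gradient in degrees from the Horn 3x3 finite-difference stencil."""
    _require_dem(dem)
    z = dem.nan_values()
    dzdx, dzdy = _horn_gradients(z, dem.cell_size)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.like(deg)


def tan_slope(dem: Raster, floor: float = 1e-3) -> np.ndarray:
    """tan(beta) from the Horn stencil, floored to keep TWI finite on flats."""
    z = dem.nan_values()
    dzdx, dzdy = _horn_gradients(z, dem.cell_size)
    return np.maximum(np.hypot(dzdx, dzdy), floor)


def tpi(dem: Raster, window_m: float = 100.0) -> Raster:
    """Topographic position index: cell elevation minus neighbourhood mean.

    The neighbourhood is the square window of side ``window_m`` (at least
    3x3 cells), centre cell excluded. Positive values are ridges, negative
    valleys, ~0 flat terrain or constant slopes.
    """
    _require_dem(dem)
    if window_m < dem.cell_size:
        raise RasterError(
            f"TPI window {window_m} m is smaller than one cell ({dem.cell_size} m)"
        )
    w = max(3, int(round(window_m / dem.cell_size)))
    if w % 2 == 0:
        w += 1
    kernel = np.ones((w, w))
    kernel[w // 2, w // 2] = 0.0
    kernel /= kernel.sum()
    z = dem.nan_values()
    neigh = ndimage.correlate(z, kernel, mode="nearest")
    return dem.like(z - neigh)


# ---------------------------------------------------------------------------
# Sink filling, D8 flow, TWI
# ---------------------------------------------------------------------------

@dataclass
class FlowField:
    """D8 drainage: per-cell receiver direction and contributing area (m^2)."""

    direction: np.ndarray  # index into the D8 offset table, -1 = outlet
    contributing_area: np.ndarray  # m^2, includes the cell's own area


def fill_sinks(dem: Raster, epsilon: float = 1e-4) -> np.ndarray:
    """Priority-flood depression filling with a tiny gradient ``epsilon``.

    Returns the filled elevation array. Every cell afterwards has a strictly
    descending D8 path to the grid border, so single-direction routing is
    well defined even across filled flats.
    """
    _require_dem(dem)
    z = dem.nan_values()
    nr, nc = z.shape
    filled = np.full_like(z, np.nan)
    closed = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    order = 0
    for r in range(nr):
        for c in range(nc):
            if (r in (0, nr - 1) or c in (0, nc - 1)) and np.isfinite(z[r, c]):
                heapq.heappush(heap, (z[r, c], order, r, c))
                order += 1
                closed[r, c] = True
    while heap:
        elev, _, r, c = heapq.heappop(heap)
        filled[r, c] = elev
        for dr, dc in _D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc] and np.isfinite(z[rr, cc]):
                closed[rr, cc] = True
                heapq.heappush(heap, (max(z[rr, cc], elev + epsilon), order, rr, cc))
                order += 1
    return filled


def d8_flow(dem: Raster, filled: np.ndarray | None = None) -> FlowField:
    """Single-direction (D8) flow routing on the sink-filled DEM.

    Each cell drains to its steepest-descent neighbour (slope = drop /
    centre distance; ties broken by the fixed neighbour order). Contributing
    areas are accumulated in decreasing elevation order and include the
    cell's own area, so area >= cell_area everywhere.
    """
    if filled is None:
        filled = fill_sinks(dem)
    nr, nc = filled.shape
    cs = dem.cell_size
    direction = np.full((nr, nc), -1, dtype=np.int8)
    valid = np.isfinite(filled)
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            best, best_k = 0.0, -1
            for k, (dr, dc) in enumerate(_D8):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and valid[rr, cc]:
                    dist = cs * math.hypot(dr, dc)
                    grad = (filled[r, c] - filled[rr, cc]) / dist
                    if grad > best:
                        best, best_k = grad, k
            direction[r, c] = best_k
    area = np.where(valid, cs * cs, np.nan)
    flat = np.argsort(filled, axis=None, kind="stable")[::-1]  # high to low
    for idx in flat:
        r, c = divmod(int(idx), nc)
        if not valid[r, c] or direction[r, c] < 0:
            continue
        dr, dc = _D8[direction[r, c]]
        area[r + dr, c + dc] += area[r, c]
    return FlowField(direction=direction, contributing_area=area)


def twi(dem: Raster, tan_beta_floor: float = 1e-3) -> Raster:
    """Topographic wetness index ln(a / tan beta).

    ``a`` is the specific contributing area (D8 contributing area divided by
    the cell width) after priority-flood sink filling; ``tan beta`` is the
    Horn-stencil slope of the filled surface, floored at
    ``tan_beta_floor`` so flat cells stay finite.
    """
    _require_dem(dem)
    filled = fill_sinks(dem)
    flow = d8_flow(dem, filled)
    a = flow.contributing_area / dem.cell_size
    tanb = np.maximum(
        np.hypot(*_horn_gradients(filled, dem.cell_size)), tan_beta_floor
    )
    return dem.like(np.log(a / tanb))


# ---------------------------------------------------------------------------
# Wind exposure (horizon-based index)
# ---------------------------------------------------------------------------

def _shift_edge(z: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift the array by (dr, dc) cells with edge replication."""
    nr, nc = z.shape
    rows = np.clip(np.arange(nr) + dr, 0, nr - 1)
    cols = np.clip(np.arange(nc) + dc, 0, nc - 1)
    return z[np.ix_(rows, cols)]


def wind_exposure(
    dem: Raster,
    n_directions: int = 8,
    search_radius_m: float = 300.0,
    bounds: tuple[float, float] = (0.5, 1.5),
) -> Raster:
    """Horizon-based wind-exposure index.

    For each direction the maximum angle to the terrain within the search
    radius is found: positive (terrain above, sheltered) or negative (all
    terrain below, exposed). The directional index ``1 - (2/pi) * angle``
    is averaged over directions and clipped to ``bounds``, giving exactly
    1.0 on flat terrain, > 1 on exposed summits and < 1 in shadowed pits.

    This is a documented surrogate for GIS wind-effect indices: same
    contract (dimensionless, flat = 1, shadow < 1, exposed > 1, averaged
    over an angular sweep), simpler auditable geometry.
    """
    _require_dem(dem)
    if n_directions < 4:
        raise RasterError(f"need >= 4 directions, got {n_directions}")
    cs = dem.cell_size
    if search_radius_m < cs:
        raise RasterError(
            f"search radius {search_radius_m} m is below one cell ({cs} m)"
        )
    z = dem.nan_values()
    n_steps = max(1, int(search_radius_m // cs))
    index_sum = np.zeros_like(z)
    for d in range(n_directions):
        theta = 2.0 * math.pi * d / n_directions
        ux, uy = math.cos(theta), math.sin(theta)
        max_angle = np.full_like(z, -np.inf)
        for k in range(1, n_steps + 1):
            dc = int(round(k * ux))
            dr = int(round(-k * uy))  # +y is north = row decrease
            if dr == 0 and dc == 0:
                continue
            dist = cs * math.hypot(dr, dc)
            angle = np.arctan((_shift_edge(z, dr, dc) - z) / dist)
            np.maximum(max_angle, angle, out=max_angle)
        max_angle[~np.isfinite(max_angle)] = 0.0
        index_sum += 1.0 - (2.0 / math.pi) * max_angle
    index = np.clip(index_sum / n_directions, *bounds)
    index[np.isnan(z)] = np.nan
    return dem.like(index)


# ---------------------------------------------------------------------------
# Forest-edge distance
# ---------------------------------------------------------------------------

def distance_from_edge(forest_mask: Raster) -> Raster:
    """Euclidean distance (m) from each forest cell to the nearest non-forest cell.

    Forest cells adjacent to non-forest get distance = one cell size (cell
    centre to cell centre); non-forest cells are nodata. A mask without any
    non-forest cell has no edge and is rejected.
    """
    vals = forest_mask.values
    forest = (vals == 1) & forest_mask.mask
    nonforest = forest_mask.mask & ~forest
    if not nonforest.any():
        raise RasterError("forest mask has no non-forest cells: edge undefined")
    # distance to the nearest cell that is valid non-forest
    dist = ndimage.distance_transform_edt(
        ~nonforest, sampling=forest_mask.cell_size
    )
    out = np.where(forest, dist, np.nan)
    return forest_mask.like(out)


# ---------------------------------------------------------------------------
# Least-cost walking time from the road network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WalkParams:
    """Naismith-style walking-cost constants (seconds per metre)."""

    flat_s_per_m: float = 0.72  # ~5 km/h on the flat
    uphill_s_per_m: float = 6.0  # ~+1 h per 600 m climbed
    downhill_s_per_m: float = 0.0


def cost_surface(
    road_mask: Raster, dem: Raster, params: WalkParams | None = None
) -> Raster:
    """Least-cost walking time (s) from the road set to every cell.

    Shortest path on the 8-connected grid; a step from cell i to j costs
    ``dist * flat + max(dz, 0) * uphill + max(-dz, 0) * downhill`` with dz
    the elevation gain. Road cells cost 0; cells unreachable from any road
    are nodata.
    """
    if not road_mask.same_grid(dem):
        raise RasterError("road mask and DEM are on different grids")
    params = params or WalkParams()
    z = dem.nan_values()
    nr, nc = z.shape
    roads = (road_mask.values == 1) & road_mask.mask & np.isfinite(z)
    if not roads.any():
        raise RasterError("no road cells in the road mask")
    valid = np.isfinite(z)
    n = nr * nc
    rows_i, cols_i, weights = [], [], []
    cs = dem.cell_size
    zf = z.ravel()
    idx = np.arange(n).reshape(nr, nc)
    for dr, dc in _D8:
        src = idx[max(0, -dr): nr - max(0, dr), max(0, -dc): nc - max(0, dc)].ravel()
        dst = idx[max(0, dr): nr + min(0, dr) or nr, max(0, dc): nc + min(0, dc) or nc].ravel()
        ok = valid.ravel()[src] & valid.ravel()[dst]
        src, dst = src[ok], dst[ok]
        dz = zf[dst] - zf[src]
        w = (
            cs * math.hypot(dr, dc) * params.flat_s_per_m
            + np.maximum(dz, 0.0) * params.uphill_s_per_m
            + np.maximum(-dz, 0.0) * params.downhill_s_per_m
        )
        rows_i.append(src)
        cols_i.append(dst)
        weights.append(w)
    graph = sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n, n),
    )
    sources = idx[roads]
    cost = _dijkstra(graph, directed=True, indices=sources, min_only=True)
    cost = cost.reshape(nr, nc)
    cost[~valid] = np.nan
    cost[np.isinf(cost)] = np.nan
    return dem.like(cost)
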