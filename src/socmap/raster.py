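"""Gridded data model and plain-text raster I/O.

All maps in the pipeline are carried by :class:`Raster`: a single-band,
regularly gridded field in a projected coordinate reference system with a
nodata sentinel. Rasters are stored on disk as ESRI ASCII grids (``.asc``),
a widely supported plain-text raster format, with the CRS identifier in a
``.crs`` sidecar file next to the grid.

Grid convention: row 0 is the northernmost row; a point (x, y) belongs to
the cell whose half-open interval ``[x0 + c*cs, x0 + (c+1)*cs)`` x
``(y0 - (r+1)*cs, y0 - r*cs]`` contains it, where (x0, y0) is the grid's
top-left (north-west) corner and ``cs`` the cell size in metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GridTransform",
    "Raster",
    "CovariateStack",
    "read_raster",
    "write_raster",
    "align_stack",
]

#: EPSG codes of common geographic (lat/lon, degree-unit) systems. The
#: pipeline computes areas and distances in metres, so these are rejected.
_GEOGRAPHIC_EPSG = {"EPSG:4326", "EPSG:4258", "EPSG:4269", "EPSG:4617", "EPSG:4283"}

SCORPAN_FACTORS = frozenset("scorpan")


class RasterError(ValueError):
    """Raised for malformed rasters, misaligned grids or bad raster files."""


@dataclass(frozen=True)
class GridTransform:
    """Affine geo-referencing of a north-up grid: top-left corner + cell size."""

    x_origin: float  # west edge of the grid (m)
    y_origin: float  # north edge of the grid (m)
    cell_size: float  # cell side length (m), square cells

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise RasterError(f"cell size must be > 0, got {self.cell_size}")

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing the point (x, y)."""
        col = math.floor((x - self.x_origin) / self.cell_size)
        row = math.floor((self.y_origin - y) / self.cell_size)
        # points exactly on the north/west edge belong to row/col 0
        if y == self.y_origin:
            row = 0
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y


def _check_crs(crs_id: str, name: str = "raster") -> str:
    crs = crs_id.strip().upper()
    if not crs:
        raise RasterError(f"{name}: missing CRS identifier")
    if crs in _GEOGRAPHIC_EPSG:
        raise RasterError(
            f"{name}: geographic CRS {crs} not supported; a projected CRS "
            "with metre units (e.g. EPSG:32644) is required because cell "
            "areas and distances are computed in metres"
        )
    return crs


@dataclass
class Raster:
    """A single-band grid of real values with nodata sentinel.

    ``values`` always stores float64; nodata cells hold ``nodata`` (NaNs
    passed in are normalised to the sentinel on construction).
    """

    values: np.ndarray
    transform: GridTransform
    crs_id: str
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RasterError(f"raster values must be 2-D, got ndim={self.values.ndim}")
        self.crs_id = _check_crs(self.crs_id)
        # normalise NaN to the sentinel so a raster has one nodata encoding
        nan = np.isnan(self.values)
        if nan.any():
            self.values = self.values.copy()
            self.values[nan] = self.nodata

    # -- basic queries ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        return self.values != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def nan_values(self) -> np.ndarray:
        """Values with nodata as NaN (convenient for numpy reductions)."""
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """A new raster on this grid carrying ``values``."""
        return Raster(
            values=values,
            transform=self.transform,
            crs_id=self.crs_id,
            nodata=self.nodata if nodata is None else nodata,
        )

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs_id == other.crs_id
        )

    def contains(self, x: float, y: float) -> bool:
        r, c = self.transform.cell_of(x, y)
        nr, nc = self.shape
        return 0 <= r < nr and 0 <= c < nc

    def value_at(self, x: float, y: float) -> float:
        r, c = self.transform.cell_of(x, y)
        return float(self.values[r, c])


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid + CRS sidecar
# ---------------------------------------------------------------------------

def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write as an ESRI ASCII grid with a ``.crs`` sidecar.

    Values are printed with 17 significant digits so that the write->read
    roundtrip reproduces float64 values bit-exactly.
    """
    path = Path(path)
    nrows, ncols = raster.shape
    t = raster.transform
    yll = t.y_origin - nrows * t.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.x_origin!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {t.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")
    path.with_suffix(path.suffix + ".crs").write_text(raster.crs_id + "\n")
    return path


def read_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster`.

    The CRS is taken from the ``.crs`` sidecar; a grid without one is
    rejected, naming the offending layer.
    """
    path = Path(path)
    if not path.exists():
        raise RasterError(f"raster file not found: {path}")
    crs_path = path.with_suffix(path.suffix + ".crs")
    if not crs_path.exists():
        raise RasterError(f"{path.name}: missing CRS sidecar {crs_path.name}")
    crs_id = _check_crs(crs_path.read_text().strip(), name=path.name)

    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=np.float64))
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise RasterError(f"{path.name}: missing header fields {sorted(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.vstack(rows) if rows else np.empty((0, ncols))
    if values.shape != (nrows, ncols):
        raise RasterError(
            f"{path.name}: data block {values.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    cs = header["cellsize"]
    transform = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cs,
        cell_size=cs,
    )
    return Raster(
        values=values,
        transform=transform,
        crs_id=crs_id,
        nodata=header.get("nodata_value", -9999.0),
    )


# ---------------------------------------------------------------------------
# Covariate stacks
# ---------------------------------------------------------------------------

@dataclass
class CovariateStack:
    """Named, grid-aligned covariate layers with scorpan role tags.

    ``roles`` maps each layer to one factor tag in {s, c, o, r, p, a, n};
    ``kinds`` marks each layer continuous or categorical (integer codes).
    """

    layers: dict[str, Raster]
    roles: dict[str, str] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise RasterError("covariate stack needs at least one layer")
        names = list(self.layers)
        ref_name, ref = names[0], self.layers[names[0]]
        for name in names[1:]:
            lay = self.layers[name]
            if not ref.same_grid(lay):
                raise RasterError(
                    f"layer '{name}' is not aligned with '{ref_name}': "
                    f"shape {lay.shape} vs {ref.shape}, transform "
                    f"{lay.transform} vs {ref.transform}, CRS {lay.crs_id} "
                    f"vs {ref.crs_id}"
                )
        for name in names:
            role = self.roles.setdefault(name, "n")
            if role not in SCORPAN_FACTORS:
                raise RasterError(
                    f"layer '{name}': role '{role}' not a scorpan factor tag"
                )
            kind = self.kinds.setdefault(name, "continuous")
            if kind not in {"continuous", "categorical"}:
                raise RasterError(f"layer '{name}': unknown kind '{kind}'")
            if kind == "categorical":
                vals = self.layers[name].valid_values()
                if vals.size and not np.allclose(vals, np.round(vals)):
                    raise RasterError(
                        f"categorical layer '{name}' holds non-integer codes"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == "continuous"]

    def categorical_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds[n] == "categorical"]

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers


def align_stack(
    layers: dict[str, Raster],
    roles: dict[str, str] | None = None,
    kinds: dict[str, str] | None = None,
) -> CovariateStack:
    """Assemble aligned layers into a :class:`CovariateStack`.

    Any layer whose grid (shape, transform or CRS) differs from the first
    layer's is rejected by name — the pipeline never resamples silently.
    """
    return CovariateStack(
        layers=dict(layers), roles=dict(roles or {}), kinds=dict(kinds or {})
    )
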