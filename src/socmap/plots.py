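"""Plot tables: georeferenced SOC observations with cluster ids.

A plot table is a pandas DataFrame with columns ``plot_id``, ``cluster_id``,
``x``, ``y`` (projected CRS, metres) and ``soc_t_ha`` (topsoil SOC stock
density, t C ha^-1, 0-30 cm). Serialised as plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .raster import CovariateStack, RasterError

PLOT_COLUMNS = ["plot_id", "cluster_id", "x", "y", "soc_t_ha"]

__all__ = ["PLOT_COLUMNS", "validate_plots", "read_plots", "write_plots", "extract_at_plots"]


def validate_plots(plots: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLOT_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table is missing columns {missing}")
    if plots["plot_id"].duplicated().any():
        dupes = plots.loc[plots["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValueError(f"duplicate plot ids: {dupes[:5]}")
    if plots["cluster_id"].isna().any() or (plots["cluster_id"].astype(str) == "").any():
        raise ValueError("every plot needs a non-empty cluster_id")
    if (plots["soc_t_ha"] < 0).any():
        bad = plots.loc[plots["soc_t_ha"] < 0, "plot_id"].tolist()
        raise ValueError(f"negative SOC for plots {bad[:5]}; SOC is a stock, must be >= 0")
    return plots


def write_plots(plots: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_plots(plots)
    plots.to_csv(path, index=False, columns=PLOT_COLUMNS, float_format="%.17g")
    return path


def read_plots(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plot table not found: {path}")
    plots = pd.read_csv(
        path,
        dtype={"plot_id": str, "cluster_id": str, "x": float, "y": float, "soc_t_ha": float},
        float_precision="round_trip",
    )
    return validate_plots(plots)


def extract_at_plots(stack: CovariateStack, plots: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell covariate extraction: one row per plot, one column per layer.

    Rows whose cell holds nodata in any layer are flagged in the boolean
    ``missing`` column rather than silently dropped. Plots outside the grid
    extent are an error listing the offending plot ids.
    """
    grid = stack.grid
    nr, nc = grid.shape
    rows = np.empty(len(plots), dtype=np.int64)
    cols = np.empty(len(plots), dtype=np.int64)
    outside = []
    for i, (pid, x, y) in enumerate(zip(plots["plot_id"], plots["x"], plots["y"])):
        r, c = grid.transform.cell_of(float(x), float(y))
        if not (0 <= r < nr and 0 <= c < nc):
            outside.append(pid)
        else:
            rows[i], cols[i] = r, c
    if outside:
        raise RasterError(f"plots outside the covariate grid extent: {outside}")

    out = pd.DataFrame(index=plots.index)
    missing = np.zeros(len(plots), dtype=bool)
    for name, layer in stack.layers.items():
        vals = layer.values[rows, cols]
        bad = vals == layer.nodata
        missing |= bad
        vals = vals.copy()
        vals[bad] = np.nan
        out[name] = vals
    out.insert(0, "plot_id", plots["plot_id"].to_numpy())
    out["missing"] = missing
    return out
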