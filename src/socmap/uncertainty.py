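"""Gridded prediction, uncertainty maps and national stock totals.

Per-cell products: the conditional mean and SD of the fitted quantile
regression forest (model uncertainty); the sampling-design sensitivity,
i.e. the per-cell SD across the k prediction maps obtained by refitting on
each spatial-CV training set; and the combined relative error

    percent_error = 100 * (model_sd + sensitivity_sd) / mean

Totals: the national stock is the sum of per-cell density times cell area
(reported in Mt C), with the combined per-cell errors aggregated either
assuming independence (root sum of squares) or full correlation (plain
sum) — the truth lies between the two.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import FoldSpec
from .qrf import QRFParams, QRForest
from .raster import CovariateStack, Raster, RasterError

logger = logging.getLogger(__name__)

__all__ = [
    "UncertaintyMaps",
    "StockEstimate",
    "predict_map",
    "sensitivity_map",
    "percent_error_map",
    "national_total",
]


@dataclass
class UncertaintyMaps:
    """Mean prediction plus its error components, all on the forest grid."""

    mean: Raster
    model_sd: Raster
    sensitivity_sd: Raster
    percent_error: Raster

    def __post_init__(self) -> None:
        for name in ("model_sd", "sensitivity_sd", "percent_error"):
            if not self.mean.same_grid(getattr(self, name)):
                raise RasterError(f"uncertainty map '{name}' not aligned with mean")


@dataclass
class StockEstimate:
    """Total stock over the mask with aggregated standard error."""

    total_mt: float
    se_mt: float
    se_percent: float
    cell_count: int
    cell_area_ha: float
    se_mode: str  # "independence" | "correlated"


def _design_from_stack(
    stack: CovariateStack, features: list[str], cells: tuple[np.ndarray, np.ndarray]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design table for the given cells; second return marks rows with nodata."""
    missing_layers = [f for f in features if f not in stack]
    if missing_layers:
        raise RasterError(f"model covariates missing from stack: {missing_layers}")
    rows, cols = cells
    data = {}
    ok = np.ones(rows.size, dtype=bool)
    for f in features:
        layer = stack[f]
        vals = layer.values[rows, cols]
        bad = vals == layer.nodata
        ok &= ~bad
        vals = vals.copy()
        vals[bad] = np.nan
        data[f] = vals
    return pd.DataFrame(data), ok


def predict_map(
    forest: QRForest, stack: CovariateStack, mask: Raster, chunk: int = 200_000
) -> tuple[Raster, Raster]:
    """Conditional mean and SD rasters over the masked cells.

    Cells outside the mask, or with nodata in any model covariate, are
    nodata in both outputs.
    """
    if not mask.same_grid(stack.grid):
        raise RasterError("mask is not aligned with the covariate stack")
    sel = mask.mask & (mask.values == 1)
    rows, cols = np.nonzero(sel)
    design, ok = _design_from_stack(stack, forest.feature_names_, (rows, cols))
    mean_map = np.full(mask.shape, np.nan)
    sd_map = np.full(mask.shape, np.nan)
    if ok.any():
        mean, sd = forest.predict_mean_sd(design[ok], chunk=chunk)
        mean_map[rows[ok], cols[ok]] = mean
        sd_map[rows[ok], cols[ok]] = sd
    return mask.like(mean_map), mask.like(sd_map)


def sensitivity_map(
    plots: pd.DataFrame,
    design: pd.DataFrame,
    stack: CovariateStack,
    folds: FoldSpec,
    params: QRFParams,
    mask: Raster,
    categorical: list[str] | None = None,
) -> Raster:
    """Sampling-design sensitivity: per-cell SD over k refit prediction maps.

    One forest is fitted per spatial fold's training set (the k
    leave-location-out realisations); the per-cell sample SD across the k
    mean maps measures how much the map depends on which clusters were
    sampled. k = 10 is the conventional choice; other k are allowed with a
    warning.
    """
    if folds.mode != "spatial":
        warnings.warn("sensitivity is defined for spatial (cluster) folds")
    if folds.k != 10:
        warnings.warn(f"sensitivity conventionally uses 10 folds, got {folds.k}")
    y = plots["soc_t_ha"].to_numpy(dtype=float)
    total = np.zeros(mask.shape)
    total2 = np.zeros(mask.shape)
    count = np.zeros(mask.shape, dtype=int)
    for fold in range(folds.k):
        tr = folds.train_indices(fold)
        forest = QRForest(params=params, categorical=categorical)
        forest.fit(design.iloc[tr], y[tr])
        mean_r, _ = predict_map(forest, stack, mask)
        vals = mean_r.nan_values()
        good = np.isfinite(vals)
        total[good] += vals[good]
        total2[good] += vals[good] ** 2
        count[good] += 1
    out = np.full(mask.shape, np.nan)
    full = count == folds.k
    k = float(folds.k)
    var = (total2[full] - total[full] ** 2 / k) / (k - 1.0)
    out[full] = np.sqrt(np.maximum(var, 0.0))
    return mask.like(out)


def percent_error_map(
    mean: Raster,
    model_sd: Raster,
    sensitivity_sd: Raster,
    mean_floor: float = 1.0,
) -> Raster:
    """Combined relative error, percent: 100 * (model SD + sensitivity SD) / mean.

    Cells whose mean is at or below ``mean_floor`` (t C ha^-1) would blow up
    the ratio and are set to nodata (count logged).
    """
    for name, r in (("model_sd", model_sd), ("sensitivity_sd", sensitivity_sd)):
        if not mean.same_grid(r):
            raise RasterError(f"'{name}' is not aligned with the mean raster")
    m = mean.nan_values()
    msd = model_sd.nan_values()
    ssd = sensitivity_sd.nan_values()
    valid = np.isfinite(m) & np.isfinite(msd) & np.isfinite(ssd)
    floored = valid & (m <= mean_floor)
    if floored.any():
        logger.info(
            "percent error: %d cells with mean <= %.3g t/ha set to nodata",
            int(floored.sum()), mean_floor,
        )
    out = np.full(mean.shape, np.nan)
    good = valid & ~floored
    out[good] = 100.0 * (msd[good] + ssd[good]) / m[good]
    return mean.like(out)


def national_total(
    maps: UncertaintyMaps,
    cell_area_ha: float | None = None,
    se_mode: str = "independence",
) -> StockEstimate:
    """Total stock (Mt C) and aggregated SE over all valid mean cells.

    Per-cell SE = (model SD + sensitivity SD) * cell area. Aggregation in
    ``independence`` mode is the root sum of squares; ``correlated`` mode is
    the plain sum (fully correlated errors). Sums are computed with
    compensated (fsum) summation in fixed row-major order, so the total is
    bit-for-bit reproducible from the written rasters.
    """
    if se_mode not in {"independence", "correlated"}:
        raise ValueError(f"unknown SE mode '{se_mode}'")
    mean = maps.mean
    if cell_area_ha is None:
        cell_area_ha = (mean.cell_size / 100.0) ** 2  # m^2 -> ha
    m = mean.nan_values()
    msd = maps.model_sd.nan_values()
    ssd = maps.sensitivity_sd.nan_values()
    valid = np.isfinite(m)
    if not valid.any():
        raise RasterError("no valid cells: cannot total an empty map")
    mv = m[valid]  # row-major order by construction
    sev = np.where(np.isfinite(msd[valid]), msd[valid], 0.0) + np.where(
        np.isfinite(ssd[valid]), ssd[valid], 0.0
    )
    total_t = math.fsum(mv.tolist()) * cell_area_ha
    se_cells = sev * cell_area_ha
    if se_mode == "independence":
        se_t = math.sqrt(math.fsum((se_cells ** 2).tolist()))
    else:
        se_t = math.fsum(se_cells.tolist())
    total_mt = total_t / 1e6
    se_mt = se_t / 1e6
    return StockEstimate(
        total_mt=total_mt,
        se_mt=se_mt,
        se_percent=100.0 * se_t / total_t if total_t > 0 else float("inf"),
        cell_count=int(valid.sum()),
        cell_area_ha=float(cell_area_ha),
        se_mode=se_mode,
    )
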