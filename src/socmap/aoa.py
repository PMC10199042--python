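"""Dissimilarity index (DI) and area of applicability (AOA).

A prediction cell is trustworthy only if it resembles the training data in
predictor space. The DI of a query point is its minimum importance-weighted
standardized Euclidean distance to any training point, normalized by the
mean pairwise distance among training points. The AOA is the set of cells
whose DI does not exceed a threshold derived from the training data itself:
the 0.95 quantile of cross-validated training DIs, where each plot's DI is
computed against the training plots outside its own fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .cv import FoldSpec
from .raster import CovariateStack, Raster, RasterError

__all__ = ["AOAResult", "DIModel", "compute_di", "compute_threshold", "aoa_mask", "aoa_analysis"]

DEFAULT_DI_QUANTILE = 0.95


@dataclass
class DIModel:
    """Frozen standardization/weighting/normalization of the DI space."""

    features: list[str]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray  # normalized to mean 1
    norm_constant: float  # mean pairwise weighted training distance


@dataclass
class AOAResult:
    di: Raster
    aoa: Raster
    threshold: float
    training_di: np.ndarray


def _prepare_weights(features: list[str], importance: pd.Series | dict | None) -> np.ndarray:
    if importance is None:
        w = np.ones(len(features))
    else:
        imp = pd.Series(importance)
        missing = [f for f in features if f not in imp.index]
        if missing:
            raise ValueError(f"no importance weight for features {missing}")
        w = np.maximum(imp[features].to_numpy(dtype=float), 0.0)
    if not (w > 0).any():
        raise ValueError("all importance weights are zero: DI undefined")
    return w / w.mean()  # scale-free: doubling all weights changes nothing


def fit_di_model(
    training: pd.DataFrame,
    features: list[str],
    importance: pd.Series | dict | None = None,
) -> DIModel:
    """Standardization + weighting learned from the training table.

    Zero-variance covariates carry no distance information and are dropped
    with a warning. Continuous covariates only: standardization absorbs any
    affine rescaling of a covariate, making the DI unit-free.
    """
    feats = list(features)
    X = training[feats].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [f for f, k in zip(feats, keep) if not k]
        warnings.warn(f"zero-variance covariates excluded from DI: {dropped}")
        feats = [f for f, k in zip(feats, keep) if k]
        X, means, sds = X[:, keep], means[keep], sds[keep]
    if not feats:
        raise ValueError("no covariates with positive variance for DI")
    weights = _prepare_weights(feats, importance)
    Z = (X - means) / sds * weights
    if len(Z) < 2:
        raise ValueError("need at least 2 training points for DI normalization")
    norm = float(pdist(Z).mean())
    if norm == 0:
        raise ValueError("all training points identical: DI normalization is 0")
    return DIModel(features=feats, means=means, sds=sds, weights=weights, norm_constant=norm)


def _transform(model: DIModel, table: pd.DataFrame) -> np.ndarray:
    X = table[model.features].to_numpy(dtype=float)
    return (X - model.means) / model.sds * model.weights


def compute_di(
    training: pd.DataFrame,
    query: pd.DataFrame,
    features: list[str],
    importance: pd.Series | dict | None = None,
    model: DIModel | None = None,
) -> np.ndarray:
    """DI of each query row: min weighted distance to training, normalized."""
    if model is None:
        model = fit_di_model(training, features, importance)
    tree = cKDTree(_transform(model, training))
    dmin, _ = tree.query(_transform(model, query), k=1)
    return np.asarray(dmin) / model.norm_constant


def compute_threshold(
    training: pd.DataFrame,
    folds: FoldSpec,
    features: list[str],
    importance: pd.Series | dict | None = None,
    quantile: float = DEFAULT_DI_QUANTILE,
) -> tuple[float, np.ndarray, DIModel]:
    """Cross-validated DI threshold.

    Each training plot's DI is its distance to the nearest training plot
    outside its own fold (the plot's cluster group is held out, mimicking
    prediction at unsampled locations); the threshold is the inclusive
    empirical ``quantile`` of these values. Returns (threshold,
    per-plot CV DI, frozen DI model).
    """
    model = fit_di_model(training, features, importance)
    n = len(training)
    di = np.empty(n)
    Z = _transform(model, training)
    for fold in range(folds.k):
        te = folds.test_indices(fold)
        tr = folds.train_indices(fold)
        if tr.size == 0:
            raise ValueError(f"fold {fold} holds every plot; CV DI undefined")
        tree = cKDTree(Z[tr])
        dmin, _ = tree.query(Z[te], k=1)
        di[te] = dmin / model.norm_constant
    # inclusive empirical quantile: smallest value with cum. fraction >= q
    srt = np.sort(di)
    idx = max(int(np.ceil(quantile * n)) - 1, 0)
    return float(srt[idx]), di, model


def aoa_mask(di_raster: Raster, threshold: float) -> Raster:
    """Binary AOA: 1 where DI <= threshold, 0 above, nodata propagated."""
    if threshold < 0:
        raise ValueError("DI threshold must be >= 0")
    di = di_raster.nan_values()
    out = np.where(di <= threshold, 1.0, 0.0)
    out[~np.isfinite(di)] = np.nan
    return di_raster.like(out)


def aoa_analysis(
    training: pd.DataFrame,
    stack: CovariateStack,
    mask: Raster,
    folds: FoldSpec,
    features: list[str] | None = None,
    importance: pd.Series | dict | None = None,
    quantile: float = DEFAULT_DI_QUANTILE,
) -> AOAResult:
    """Full AOA screening over the masked grid.

    Continuous covariates only enter the distance (standardization is
    undefined for unordered codes); importance weights usually come from
    the forest's permutation importance.
    """
    if not mask.same_grid(stack.grid):
        raise RasterError("mask is not aligned with the covariate stack")
    if features is None:
        features = [f for f in stack.continuous_names() if f in training.columns]
    threshold, train_di, model = compute_threshold(
        training, folds, features, importance, quantile
    )
    sel = mask.mask & (mask.values == 1)
    rows, cols = np.nonzero(sel)
    query = {}
    ok = np.ones(rows.size, dtype=bool)
    for f in model.features:
        layer = stack[f]
        vals = layer.values[rows, cols]
        bad = vals == layer.nodata
        ok &= ~bad
        query[f] = vals
    qdf = pd.DataFrame(query)
    di_map = np.full(mask.shape, np.nan)
    if ok.any():
        di_vals = compute_di(training, qdf[ok], model.features, model=model)
        di_map[rows[ok], cols[ok]] = di_vals
    di_raster = mask.like(di_map)
    return AOAResult(
        di=di_raster,
        aoa=aoa_mask(di_raster, threshold),
        threshold=threshold,
        training_di=train_di,
    )
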