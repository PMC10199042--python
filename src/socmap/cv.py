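"""Cluster-aware and random k-fold cross-validation for clustered plot data.

Forest-inventory plots come in spatial clusters (~150 m plot spacing within
a cluster, kilometres between clusters). Random k-fold CV splits clusters
between training and test sets, so spatially correlated noise shared by a
cluster leaks across the split and makes the map look better than it is.
Leave-location-out (spatial) CV assigns whole clusters to folds: no cluster
is ever split, which yields the honest — typically larger — error estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field

from .qrf import QRFParams, QRForest

__all__ = [
    "FoldSpec",
    "CVResult",
    "make_spatial_folds",
    "make_random_folds",
    "rmse",
    "r_squared",
    "cross_validate",
]


@dataclass
class FoldSpec:
    """Partition of plots into k folds.

    ``assignment`` maps positional plot index -> fold number (0..k-1). In
    spatial mode all plots of a cluster share a fold.
    """

    k: int
    assignment: np.ndarray
    mode: str  # "spatial" | "random"
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment != fold)[0]


def make_spatial_folds(plots: pd.DataFrame, k: int, seed: int = 0) -> FoldSpec:
    """Leave-location-out folds: clusters dealt to folds, never split.

    Clusters are shuffled with the seed and dealt greedily to the currently
    smallest fold (by plot count), balancing fold sizes. k equal to the
    number of clusters gives leave-one-cluster-out.
    """
    clusters = plots["cluster_id"].to_numpy()
    unique = np.unique(clusters)
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if k > len(unique):
        raise ValueError(
            f"k={k} folds but only {len(unique)} clusters; folds must be "
            "groups of whole clusters"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    sizes = np.zeros(k, dtype=int)
    cluster_fold: dict[str, int] = {}
    for ci in order:
        cid = unique[ci]
        fold = int(np.argmin(sizes))  # ties -> lowest fold index
        cluster_fold[cid] = fold
        sizes[fold] += int((clusters == cid).sum())
    assignment = np.array([cluster_fold[c] for c in clusters])
    return FoldSpec(k=k, assignment=assignment, mode="spatial", seed=seed)


def make_random_folds(plots: pd.DataFrame, k: int, seed: int = 0) -> FoldSpec:
    """Plot-level random folds with sizes differing by at most one."""
    n = len(plots)
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if k > n:
        raise ValueError(f"k={k} folds but only {n} plots")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    assignment[rng.permutation(n)] = np.arange(n) % k
    return FoldSpec(k=k, assignment=assignment, mode="random", seed=seed)


def rmse(obs, pred) -> float:
    """Root mean squared error sqrt(sum (y - yhat)^2 / n)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(obs, pred) -> float:
    """1 - SSE/SST on pooled out-of-fold pairs; exactly 1 when pred == obs."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sse = np.sum((obs - pred) ** 2)
    sst = np.sum((obs - np.mean(obs)) ** 2)
    if sst == 0:
        return 1.0 if sse == 0 else -np.inf
    return float(1.0 - sse / sst)


@dataclass
class CVResult:
    """Out-of-fold predictions and summary scores for the selected model."""

    oof: pd.DataFrame  # plot_id, fold, obs, pred
    per_fold_rmse: dict[int, float]
    rmse: float
    r2: float
    params: QRFParams
    all_results: list[dict] = field(default_factory=list)

    def to_summary(self) -> dict:
        return {
            "rmse": self.rmse,
            "r2": self.r2,
            "per_fold_rmse": {str(k): v for k, v in self.per_fold_rmse.items()},
            "params": {
                "n_trees": self.params.n_trees,
                "mtry": self.params.mtry,
                "min_node_size": self.params.min_node_size,
                "seed": self.params.seed,
            },
        }


def _complexity_key(p: QRFParams) -> tuple:
    # tie-break toward parsimony: fewer trees, then larger min_node_size
    return (p.n_trees, -p.min_node_size)


def cross_validate(
    plots: pd.DataFrame,
    design: pd.DataFrame,
    folds: FoldSpec,
    param_grid: list[QRFParams] | None = None,
    categorical: list[str] | None = None,
) -> CVResult:
    """k-fold CV over a (possibly singleton) hyperparameter grid.

    For each setting, fits on k-1 folds and predicts the held-out fold;
    out-of-fold predictions are pooled and the setting with the smallest
    pooled RMSE wins (ties broken toward smaller model complexity). Every
    plot is predicted exactly once per setting.
    """
    if param_grid is None:
        param_grid = [QRFParams()]
    if not param_grid:
        raise ValueError("empty parameter grid")
    if len(plots) != len(design):
        raise ValueError("plots and design table have different lengths")
    y = plots["soc_t_ha"].to_numpy(dtype=float)

    results = []
    for params in param_grid:
        pred = np.full(len(plots), np.nan)
        fold_scores: dict[int, float] = {}
        for fold in range(folds.k):
            tr = folds.train_indices(fold)
            te = folds.test_indices(fold)
            if np.unique(y[tr]).size < 2:
                raise ValueError(
                    f"training set for fold {fold} has constant SOC; "
                    "cannot fit a forest"
                )
            forest = QRForest(params=params, categorical=categorical)
            forest.fit(design.iloc[tr], y[tr])
            mean, _ = forest.predict_mean_sd(design.iloc[te])
            pred[te] = mean
            fold_scores[fold] = rmse(y[te], mean)
        assert not np.isnan(pred).any(), "folds must partition the plots"
        results.append(
            {
                "params": params,
                "pred": pred,
                "per_fold_rmse": fold_scores,
                "rmse": rmse(y, pred),
                "r2": r_squared(y, pred),
            }
        )

    best = min(
        results, key=lambda r: (r["rmse"], _complexity_key(r["params"]))
    )
    oof = pd.DataFrame(
        {
            "plot_id": plots["plot_id"].to_numpy(),
            "fold": folds.assignment,
            "obs": y,
            "pred": best["pred"],
        }
    )
    return CVResult(
        oof=oof,
        per_fold_rmse=best["per_fold_rmse"],
        rmse=best["rmse"],
        r2=best["r2"],
        params=best["params"],
        all_results=[
            {k: v for k, v in r.items() if k != "pred"} for r in results
        ],
    )
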