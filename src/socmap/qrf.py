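"""Quantile regression forest with explicit conditional distributions.

A random forest of CART regression trees in which every leaf retains the
identities (and bootstrap multiplicities) of its in-bag training
observations. A prediction point therefore yields a full conditional
distribution over the training responses via Meinshausen leaf weights —
for each tree, mass 1 / (leaf size * n_trees) per in-bag observation
sharing the point's leaf — from which mean, SD and quantiles follow.

Tree induction (variance-reduction splits, per-split feature subsampling,
minimum leaf size) is delegated to scikit-learn's ``DecisionTreeRegressor``;
bootstrapping, in-bag/out-of-bag bookkeeping, the weight aggregation,
permutation importance and partial dependence are implemented here.

Categorical covariates are handled by target-mean ordinal encoding: for a
variance-reduction split, ordering the levels by their mean response and
splitting on that order is equivalent to exhaustive subset search (Fisher's
optimal-partition ordering). The encoding is computed per tree from the
tree's own bootstrap sample, so out-of-bag rows never contribute to the
level means they are encoded with — this keeps OOB error estimates and
permutation importances honest. A level unseen by a tree's bootstrap
sample falls back to the tree's in-bag mean response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.tree import DecisionTreeRegressor

logger = logging.getLogger(__name__)

__all__ = ["QRFParams", "QRForest", "ConditionalDistribution", "weighted_quantile"]

_FORMAT = "socmap-qrf-2"


@dataclass(frozen=True)
class QRFParams:
    """Forest hyperparameters.

    mtry defaults to ceil(p / 3) (regression-forest convention);
    min_node_size is the minimum number of bootstrap samples per leaf.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 5
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            return max(1, min(self.mtry, p))
        return max(1, int(np.ceil(p / 3.0)))


def weighted_quantile(
    y_sorted: np.ndarray, cum_weights: np.ndarray, q: float
) -> float:
    """Smallest y whose cumulative weight reaches q (inclusive, no interpolation)."""
    idx = int(np.searchsorted(cum_weights, q - 1e-9, side="left"))
    return float(y_sorted[min(idx, len(y_sorted) - 1)])


@dataclass
class ConditionalDistribution:
    """Per-point weights over the training responses.

    ``weights[i]`` is a probability vector over the training observations
    for prediction point i; quantiles use the inclusive weighted empirical
    definition (smallest response with cumulative weight >= q).
    """

    weights: np.ndarray  # (n_points, n_train)
    y: np.ndarray  # (n_train,)
    _order: np.ndarray = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._order = np.argsort(self.y, kind="stable")

    def mean(self) -> np.ndarray:
        return self.weights @ self.y

    def sd(self) -> np.ndarray:
        mu = self.mean()
        var = self.weights @ (self.y ** 2) - mu ** 2
        return np.sqrt(np.maximum(var, 0.0))

    def quantile(self, q: float | np.ndarray) -> np.ndarray:
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        ys = self.y[self._order]
        cw = np.cumsum(self.weights[:, self._order], axis=1)
        out = np.empty((self.weights.shape[0], qs.size))
        for j, qq in enumerate(qs):
            idx = np.sum(cw < qq - 1e-9, axis=1)
            out[:, j] = ys[np.minimum(idx, len(ys) - 1)]
        return out[:, 0] if np.isscalar(q) or np.asarray(q).ndim == 0 else out


class _TreeEncoder:
    """Per-tree target-mean encoding of the categorical columns."""

    def __init__(self, cat_idx: list[int], X_inbag: np.ndarray, y_inbag: np.ndarray):
        self.cat_idx = cat_idx
        self.default = float(np.mean(y_inbag))
        self.maps: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for j in cat_idx:
            codes, inverse = np.unique(X_inbag[:, j], return_inverse=True)
            means = np.bincount(inverse, weights=y_inbag) / np.bincount(inverse)
            self.maps[j] = (codes, means)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.cat_idx:
            return X
        out = X.copy()
        for j, (codes, means) in self.maps.items():
            col = X[:, j]
            pos = np.searchsorted(codes, col)
            pos_c = np.clip(pos, 0, len(codes) - 1)
            hit = codes[pos_c] == col
            out[:, j] = np.where(hit, means[pos_c], self.default)
        return out


class QRForest:
    """Quantile regression forest over a pandas design table."""

    def __init__(self, params: QRFParams | None = None, categorical: list[str] | None = None):
        self.params = params or QRFParams()
        self.categorical = list(categorical or [])
        self.fitted = False

    # ------------------------------------------------------------------
    # Fitting
    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: np.ndarray | pd.Series) -> "QRForest":
        if self.params.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        y = np.asarray(y, dtype=np.float64)
        if len(X) != len(y):
            raise ValueError("design table and response have different lengths")
        bad_rows = X.index[X.isna().any(axis=1)].tolist()
        if np.isnan(y).any():
            bad_rows += list(np.nonzero(np.isnan(y))[0])
        if bad_rows:
            raise ValueError(f"missing values in rows {sorted(set(bad_rows))[:10]}")
        if np.unique(y).size < 2:
            raise ValueError("constant response: degenerate fit (need >= 2 distinct y)")
        unknown = [c for c in self.categorical if c not in X.columns]
        if unknown:
            raise ValueError(f"categorical columns not in design table: {unknown}")

        self.feature_names_ = list(X.columns)
        self._cat_idx = [self.feature_names_.index(c) for c in self.categorical]
        self.y_ = y
        Xb = self._to_base(X)
        self._X_train_base = Xb
        n, p = Xb.shape
        mtry = self.params.resolve_mtry(p)

        ss = np.random.SeedSequence(self.params.seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
        tree_seeds = ss.generate_state(self.params.n_trees)

        self.trees_: list[DecisionTreeRegressor] = []
        self.encoders_: list[_TreeEncoder] = []
        self.inbag_: list[np.ndarray] = []  # bootstrap indices, length n
        self.oob_: list[np.ndarray] = []  # bool masks over training rows
        self._leaf_tables: list[sparse.csr_matrix] = []  # leaf -> weight over train rows
        self._leaf_mean: list[np.ndarray] = []
        self._leaf_m2: list[np.ndarray] = []

        for t in range(self.params.n_trees):
            idx = rng.integers(0, n, n)
            enc = _TreeEncoder(self._cat_idx, Xb[idx], y[idx])
            Xe_in = enc.transform(Xb[idx])
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.params.min_node_size,
                random_state=int(tree_seeds[t] % (2 ** 31)),
            )
            tree.fit(Xe_in, y[idx])
            leaves_inbag = tree.apply(Xe_in)
            n_nodes = tree.tree_.node_count
            # bootstrap multiplicity per (leaf, original row)
            mat = sparse.coo_matrix(
                (np.ones(n), (leaves_inbag, idx)), shape=(n_nodes, n)
            ).tocsr()
            leaf_total = np.asarray(mat.sum(axis=1)).ravel()
            leaf_total[leaf_total == 0] = 1.0
            weights = mat.multiply(1.0 / leaf_total[:, None]).tocsr()
            self.trees_.append(tree)
            self.encoders_.append(enc)
            self.inbag_.append(idx)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            self.oob_.append(oob)
            self._leaf_tables.append(weights)
            self._leaf_mean.append(weights @ y)
            self._leaf_m2.append(weights @ (y ** 2))
        self.fitted = True
        return self

    def _to_base(self, X: pd.DataFrame) -> np.ndarray:
        """Raw float matrix in training column order (categorical = raw codes)."""
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise ValueError(f"table is missing covariates {missing}")
        return X[self.feature_names_].to_numpy(dtype=np.float64)

    def _check_predict_input(self, X: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("forest is not fitted")
        Xb = self._to_base(X)
        if np.isnan(Xb).any():
            rows = np.nonzero(np.isnan(Xb).any(axis=1))[0]
            raise ValueError(
                f"missing covariate values in prediction rows {rows[:10].tolist()}"
            )
        return Xb

    def _apply_tree(self, t: int, Xb: np.ndarray) -> np.ndarray:
        return self.trees_[t].apply(self.encoders_[t].transform(Xb))

    # ------------------------------------------------------------------
    # Prediction
    # ------------------------------------------------------------------
    def predict_distribution(self, X: pd.DataFrame) -> ConditionalDistribution:
        """Meinshausen conditional distributions for each row of X."""
        Xb = self._check_predict_input(X)
        n_train = len(self.y_)
        acc = sparse.csr_matrix((len(Xb), n_train))
        for t in range(self.params.n_trees):
            leaves = self._apply_tree(t, Xb)
            acc = acc + self._leaf_tables[t][leaves]
        W = np.asarray(acc.todense()) / self.params.n_trees
        return ConditionalDistribution(weights=W, y=self.y_)

    def predict_mean_sd(self, X: pd.DataFrame, chunk: int = 65536) -> tuple[np.ndarray, np.ndarray]:
        """Conditional mean and SD without materialising weight vectors.

        Uses per-leaf first and second moments; identical (to float
        round-off) to the moments of :meth:`predict_distribution`.
        """
        Xb = self._check_predict_input(X)
        n = len(Xb)
        mean = np.zeros(n)
        m2 = np.zeros(n)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            block = Xb[sl]
            for t in range(self.params.n_trees):
                leaves = self._apply_tree(t, block)
                mean[sl] += self._leaf_mean[t][leaves]
                m2[sl] += self._leaf_m2[t][leaves]
        mean /= self.params.n_trees
        m2 /= self.params.n_trees
        sd = np.sqrt(np.maximum(m2 - mean ** 2, 0.0))
        return mean, sd

    def predict_quantiles(self, X: pd.DataFrame, qs) -> np.ndarray:
        return self.predict_distribution(X).quantile(np.asarray(qs, dtype=float))

    # ------------------------------------------------------------------
    # Out-of-bag machinery, importance, partial dependence
    # ------------------------------------------------------------------
    def oob_predictions(self) -> np.ndarray:
        """Per-row mean prediction from trees where the row is out of bag.

        Rows in-bag for every tree come back NaN.
        """
        if not self.fitted:
            raise RuntimeError("forest is not fitted")
        n = len(self.y_)
        total = np.zeros(n)
        count = np.zeros(n)
        for t, oob in enumerate(self.oob_):
            if not oob.any():
                continue
            leaves = self._apply_tree(t, self._X_train_base[oob])
            total[oob] += self._leaf_mean[t][leaves]
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            pred = total / count
        pred[count == 0] = np.nan
        return pred

    def _oob_rmse(self, Xb: np.ndarray) -> float:
        n = len(self.y_)
        total = np.zeros(n)
        count = np.zeros(n)
        for t, oob in enumerate(self.oob_):
            if not oob.any():
                continue
            leaves = self._apply_tree(t, Xb[oob])
            total[oob] += self._leaf_mean[t][leaves]
            count[oob] += 1
        has = count > 0
        pred = total[has] / count[has]
        return float(np.sqrt(np.mean((pred - self.y_[has]) ** 2)))

    def oob_rmse_with_permutation(
        self, X: pd.DataFrame, feature: str, permutation: np.ndarray | None = None
    ) -> float:
        """OOB RMSE after applying ``permutation`` to one feature column.

        The identity permutation (or None with no shuffle) reproduces the
        baseline OOB RMSE exactly.
        """
        Xb = self._check_predict_input(X)
        if permutation is not None:
            j = self.feature_names_.index(feature)
            Xb = Xb.copy()
            Xb[:, j] = Xb[permutation, j]
        return self._oob_rmse(Xb)

    def variable_importance(
        self, X: pd.DataFrame, n_perm: int = 5, seed: int = 0
    ) -> pd.Series:
        """Permutation importance (mean decrease accuracy) per covariate.

        The mean increase in out-of-bag RMSE after permuting the covariate,
        averaged over ``n_perm`` seeded permutations.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        Xb = self._check_predict_input(X)
        base = self._oob_rmse(Xb)
        rng = np.random.default_rng(seed)
        n = len(Xb)
        imp = {}
        for j, feat in enumerate(self.feature_names_):
            deltas = []
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Xp = Xb.copy()
                Xp[:, j] = Xb[perm, j]
                deltas.append(self._oob_rmse(Xp) - base)
            imp[feat] = float(np.mean(deltas))
        return pd.Series(imp, name="importance")

    def partial_dependence(
        self, X: pd.DataFrame, covariate: str, grid_values
    ) -> np.ndarray:
        """Mean prediction over the design with ``covariate`` set to each grid value."""
        grid_values = np.asarray(grid_values, dtype=float)
        if grid_values.size == 0:
            raise ValueError("empty partial-dependence grid")
        if covariate not in self.feature_names_:
            raise ValueError(f"unknown covariate '{covariate}'")
        lo, hi = X[covariate].min(), X[covariate].max()
        if grid_values.min() < lo or grid_values.max() > hi:
            raise ValueError(
                f"grid outside the observed range of '{covariate}' [{lo}, {hi}]"
            )
        curve = np.empty(grid_values.size)
        for i, v in enumerate(grid_values):
            Xm = X.copy()
            Xm[covariate] = v
            mean, _ = self.predict_mean_sd(Xm)
            curve[i] = float(np.mean(mean))
        return curve

    # ------------------------------------------------------------------
    # Serialization
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"format": _FORMAT, "model": self}
        joblib.dump(payload, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "QRForest":
        payload = joblib.load(path)
        if payload.get("format") != _FORMAT:
            raise ValueError(f"unsupported model format: {payload.get('format')}")
        return payload["model"]
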