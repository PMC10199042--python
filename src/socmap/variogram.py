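"""Empirical semivariograms of CV residuals with permutation envelopes.

The semivariance gamma(h) = mean of (z_i - z_j)^2 / 2 over point pairs at
separation ~h measures how dissimilar residuals are as a function of
distance. If a model has captured the spatially structured part of the
signal, its residual variogram is flat and stays inside the envelope
obtained by randomly permuting residuals over the locations (the
no-autocorrelation null); a curve exiting the envelope at short lags flags
leftover spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["VariogramResult", "empirical_variogram", "permutation_envelope"]


@dataclass
class VariogramResult:
    bin_centers: np.ndarray  # m
    gamma: np.ndarray  # semivariance per bin (NaN where no pairs)
    n_pairs: np.ndarray
    env_lo: np.ndarray | None = None
    env_hi: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None


def _bin_pairs(
    locations: np.ndarray, max_dist_m: float, n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair distances binned into regular half-open bins (lo, hi] on (0, max]."""
    locations = np.asarray(locations, dtype=float)
    if locations.ndim != 2 or locations.shape[1] != 2:
        raise ValueError("locations must be an (n, 2) array of x, y in metres")
    if len(locations) < 2:
        raise ValueError("need at least 2 locations")
    if max_dist_m <= 0:
        raise ValueError("max distance must be positive")
    d = pdist(locations)
    edges = np.linspace(0.0, max_dist_m, n_bins + 1)
    usable = (d > 0) & (d <= max_dist_m)
    # distance exactly on an edge goes to the lower bin: searchsorted 'left'
    bin_idx = np.searchsorted(edges, d[usable], side="left") - 1
    return bin_idx, usable, edges


def _gamma_from_bins(
    sqdiff: np.ndarray, bin_idx: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    sums = np.bincount(bin_idx, weights=sqdiff, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = sums / (2.0 * counts)
    gamma[counts == 0] = np.nan
    return gamma, counts


def empirical_variogram(
    locations: np.ndarray,
    residuals: np.ndarray,
    max_dist_m: float = 25_000.0,
    n_bins: int = 50,
) -> VariogramResult:
    """Semivariance over regular distance bins on (0, max_dist_m].

    gamma(bin) = sum over pairs in the bin of (z_i - z_j)^2 / (2 N_bin).
    Zero-distance pairs (co-located points) are excluded.
    """
    residuals = np.asarray(residuals, dtype=float)
    bin_idx, usable, edges = _bin_pairs(locations, max_dist_m, n_bins)
    if not usable.any():
        raise ValueError(f"no point pairs within {max_dist_m} m")
    sqdiff = pdist(residuals[:, None], metric="sqeuclidean")[usable]
    gamma, counts = _gamma_from_bins(sqdiff, bin_idx, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VariogramResult(bin_centers=centers, gamma=gamma, n_pairs=counts)


def permutation_envelope(
    locations: np.ndarray,
    residuals: np.ndarray,
    max_dist_m: float = 25_000.0,
    n_bins: int = 50,
    n_perm: int = 99,
    seed: int = 0,
) -> VariogramResult:
    """Observed variogram plus a pointwise min/max permutation envelope.

    Residual values are randomly reassigned to the locations ``n_perm``
    times; the per-bin envelope is the pointwise minimum / maximum of the
    permuted semivariances (the classical Monte-Carlo variogram envelope;
    pointwise, not simultaneous).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    residuals = np.asarray(residuals, dtype=float)
    bin_idx, usable, edges = _bin_pairs(locations, max_dist_m, n_bins)
    if not usable.any():
        raise ValueError(f"no point pairs within {max_dist_m} m")
    obs_sq = pdist(residuals[:, None], metric="sqeuclidean")[usable]
    gamma, counts = _gamma_from_bins(obs_sq, bin_idx, n_bins)

    rng = np.random.default_rng(seed)
    env_lo = np.full(n_bins, np.inf)
    env_hi = np.full(n_bins, -np.inf)
    for _ in range(n_perm):
        perm = rng.permutation(len(residuals))
        sq = pdist(residuals[perm][:, None], metric="sqeuclidean")[usable]
        g, _ = _gamma_from_bins(sq, bin_idx, n_bins)
        with np.errstate(invalid="ignore"):
            env_lo = np.fmin(env_lo, g)
            env_hi = np.fmax(env_hi, g)
    env_lo[counts == 0] = np.nan
    env_hi[counts == 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VariogramResult(
        bin_centers=centers,
        gamma=gamma,
        n_pairs=counts,
        env_lo=env_lo,
        env_hi=env_hi,
        n_permutations=n_perm,
        seed=seed,
    )
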