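"""Dimensionality of pattern space by parallel analysis.

Parallel analysis counts the principal components whose eigenvalues exceed
those of a null ensemble in which every feature's samples are independently
shuffled, destroying cross-feature covariance while keeping the marginals.
Features are standardized first, so the eigenvalues are those of the
correlation matrix and sum to the number of features. The method tends to
underestimate the true dimensionality of linear spaces above roughly 20
dimensions, so its estimate is best read as a lower-bound-flavored count of
statistically supported dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParallelAnalysisResult",
    "standardize",
    "parallel_analysis",
    "stability_curve",
    "pca_variance_dims",
]


@dataclass
class ParallelAnalysisResult:
    n_significant: int
    eigenvalues: np.ndarray
    null_quantiles: np.ndarray
    n_shuffles: int
    percentile: float


def standardize(features: np.ndarray) -> np.ndarray:
    """Column-standardize: mean 0, variance 1; constant columns are dropped
    with a warning."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 features")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features are constant")
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance feature(s)")
        X = X[:, keep]
        sd = sd[keep]
    return (X - X.mean(axis=0)) / sd


def _eigvals(X: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the correlation matrix of standardized data
    (population normalization, so the spectrum sums to the feature count)."""
    M = X.shape[0]
    s = np.linalg.svd(X, compute_uv=False)
    ev = np.zeros(X.shape[1])
    ev[: s.size] = s**2 / M
    return ev


def parallel_analysis(
    features: np.ndarray,
    n_shuffles: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> ParallelAnalysisResult:
    """Number of PCs with statistically significant explanatory power.

    A rank counts as significant when the observed eigenvalue exceeds the
    ``percentile`` of null eigenvalues at that rank; counting proceeds from
    the first rank and stops at the first failure. The null is built by an
    independent permutation within each column (a fresh permutation per
    shuffle round). Deterministic per seed.
    """
    X = standardize(features)
    M, D = X.shape
    if M < 50:
        raise ValueError("need at least 50 samples for a stable null")
    obs = _eigvals(X)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, D))
    Xs = X.copy()
    for r in range(n_shuffles):
        for j in range(D):
            Xs[:, j] = X[rng.permutation(M), j]
        null[r] = _eigvals(Xs)
    q = np.percentile(null, percentile, axis=0)
    exceeds = obs > q
    n_sig = int(np.argmin(exceeds)) if not exceeds.all() else int(exceeds.size)
    return ParallelAnalysisResult(n_sig, obs, q, n_shuffles, percentile)


def stability_curve(
    features: np.ndarray,
    sample_sizes: list[int],
    n_shuffles: int = 100,
    percentile: float = 95.0,
    n_repeats: int = 3,
    seed: int = 0,
) -> dict:
    """Parallel-analysis estimate against sample size, on nested random
    subsamples with per-size repeats."""
    X = np.asarray(features, dtype=float)
    M = X.shape[0]
    if max(sample_sizes) > M:
        raise ValueError("largest sample size exceeds available samples")
    rng = np.random.default_rng(seed)
    curve = {}
    for rep in range(n_repeats):
        order = rng.permutation(M)
        for m in sorted(sample_sizes):
            res = parallel_analysis(
                X[order[:m]], n_shuffles=n_shuffles, percentile=percentile,
                seed=int(rng.integers(2**31)),
            )
            curve.setdefault(m, []).append(res.n_significant)
    return {m: np.asarray(v) for m, v in sorted(curve.items())}


def pca_variance_dims(features: np.ndarray, variance: float = 0.90) -> int:
    """Linear benchmark: PCs needed to reach the given cumulative variance."""
    X = standardize(features)
    ev = _eigvals(X)
    frac = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(frac, variance) + 1)
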