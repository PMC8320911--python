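"""Recursively maintainable per-cluster statistics.

Each cluster keeps only three quantities: the running mean ``mu`` of its
member vectors, the running mean ``X`` of their squared Euclidean norms,
and the member count ``n``.  Together they are sufficient to evaluate the
Cauchy-kernel local density of any query point against the cluster, because
the cluster's total variance is ``X - ||mu||**2``.  Both ``mu`` and ``X``
admit an exact one-sample-at-a-time update, so member vectors never need to
be kept in memory for density evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterStats", "batch_stats", "update_stats", "merge_stats"]


@dataclass(frozen=True)
class ClusterStats:
    """Sufficient statistics of one cluster.

    Attributes
    ----------
    mu : ndarray of shape (K,)
        Arithmetic mean of the member vectors.
    X : float
        Mean of the squared Euclidean norms of the member vectors.
    n : int
        Number of members folded in so far.
    """

    mu: np.ndarray = field(repr=False)
    X: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        if self.n < 1:
            raise ValueError("a materialized cluster has at least one member")

    @property
    def dim(self) -> int:
        return int(self.mu.shape[0])

    @property
    def variance(self) -> float:
        """Total variance ``X - ||mu||**2`` (non-negative up to round-off)."""
        return float(self.X - self.mu @ self.mu)

    def allclose(self, other: "ClusterStats", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and np.allclose(self.mu, other.mu, rtol=rtol, atol=1e-12)
            and np.isclose(self.X, other.X, rtol=rtol, atol=1e-12)
        )


def batch_stats(vectors: np.ndarray) -> ClusterStats:
    """Compute cluster statistics over a whole set of vectors at once.

    This is the definitional (non-recursive) closure of the one-sample
    update: ``mu`` is the arithmetic mean and ``X`` the mean squared norm.

    Parameters
    ----------
    vectors : array-like of shape (n, K)

    Raises
    ------
    ValueError
        If the set is empty.
    """
    arr = np.asarray(vectors, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0 or arr.shape[0] == 0:
        raise ValueError("batch_stats requires at least one vector")
    mu = arr.mean(axis=0)
    X = float(np.mean(np.einsum("ij,ij->i", arr, arr)))
    return ClusterStats(mu=mu, X=X, n=arr.shape[0])


def update_stats(stats: ClusterStats, F: np.ndarray) -> ClusterStats:
    """Fold one vector into cluster statistics (value semantics).

    With ``i = n + 1`` the updates are

    .. math::

        \\mu_i = \\frac{i-1}{i}\\mu_{i-1} + \\frac{1}{i} F_i, \\qquad
        X_i   = \\frac{i-1}{i} X_{i-1} + \\frac{1}{i}\\lVert F_i\\rVert^2,

    with base case ``mu_1 = F_1``, ``X_1 = ||F_1||**2``.  Folding a stream
    this way reproduces :func:`batch_stats` of the same multiset to
    round-off, in any order.
    """
    F = np.asarray(F, dtype=np.float64).ravel()
    if F.shape[0] != stats.dim:
        raise ValueError(
            f"dimension mismatch: stats dim {stats.dim}, vector dim {F.shape[0]}"
        )
    i = stats.n + 1
    w = (i - 1) / i
    mu = w * stats.mu + F / i
    X = w * stats.X + float(F @ F) / i
    return ClusterStats(mu=mu, X=X, n=i)


def merge_stats(parts: list[ClusterStats]) -> ClusterStats:
    """Count-weighted combination of disjoint clusters' statistics.

    Exact: the result equals :func:`batch_stats` over the union of the
    parts' members.  Used to give internal tree nodes statistics over all
    their descendant leaves' members without touching the vectors.
    """
    if not parts:
        raise ValueError("merge_stats requires at least one part")
    n = sum(p.n for p in parts)
    mu = sum(p.n * p.mu for p in parts) / n
    X = sum(p.n * p.X for p in parts) / n
    return ClusterStats(mu=mu, X=float(X), n=n)
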