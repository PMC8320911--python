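"""Query path: Cauchy-kernel local density, winner-takes-all descent,
City-Block re-ranking.

The similarity between a query vector and a cluster is a Cauchy-type kernel
density evaluated from the cluster's sufficient statistics alone:

    D = 1 / (1 + ||F - mu||^2 + X - ||mu||^2)

where ``X - ||mu||^2`` is the cluster's total variance.  The search walks
the hierarchy top-down, keeping at each layer the ``beam`` densest clusters
("winner takes all" for beam 1, "few winners take all" otherwise), and
finally ranks the members of the surviving leaves by City-Block distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stats import ClusterStats

__all__ = [
    "DensityScore",
    "RankedResult",
    "QueryTrace",
    "local_density",
    "winner_cluster",
    "cityblock",
    "rank_by_cityblock",
    "descend",
    "query",
]


@dataclass(frozen=True)
class DensityScore:
    value: float
    cluster_id: int


@dataclass
class RankedResult:
    """Ordered retrieval list: (item id, City-Block distance), ascending.

    Ties in distance are broken by ascending item id, so the ordering is
    deterministic across platforms.
    """

    pairs: list[tuple[int, float]]
    query_id: object = None

    @property
    def ids(self) -> list[int]:
        return [i for i, _ in self.pairs]

    @property
    def distances(self) -> list[float]:
        return [d for _, d in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class QueryTrace:
    """Instrumentation of one query: which clusters were scored where.

    ``evaluated[l]`` lists (node id, density) for every density evaluation
    at layer ``l`` of the descent (layers top-down); ``kept[l]`` the ids
    surviving the beam at that layer.  ``n_distance_evals`` counts the
    City-Block evaluations of the final re-ranking stage.
    """

    evaluated: list[list[tuple[int, float]]] = field(default_factory=list)
    kept: list[list[int]] = field(default_factory=list)
    n_distance_evals: int = 0

    @property
    def n_density_evals(self) -> int:
        return sum(len(layer) for layer in self.evaluated)

    @property
    def total_evals(self) -> int:
        return self.n_density_evals + self.n_distance_evals

    def to_dict(self) -> dict:
        return {
            "evaluated": [[[int(i), float(d)] for i, d in layer] for layer in self.evaluated],
            "kept": [[int(i) for i in layer] for layer in self.kept],
            "n_density_evals": self.n_density_evals,
            "n_distance_evals": self.n_distance_evals,
        }


def local_density(F: np.ndarray, stats: ClusterStats) -> float:
    """Cauchy-kernel local density of a point w.r.t. a cluster, in (0, 1].

    The denominator ``1 + ||F-mu||^2 + X - ||mu||^2`` is clamped to at
    least 1: the variance term is non-negative in exact arithmetic and only
    round-off can push it below zero.
    """
    F = np.asarray(F, dtype=np.float64).ravel()
    if F.shape[0] != stats.dim:
        raise ValueError(
            f"dimension mismatch: stats dim {stats.dim}, vector dim {F.shape[0]}"
        )
    diff = F - stats.mu
    denom = 1.0 + float(diff @ diff) + stats.variance
    return 1.0 / max(denom, 1.0)


def winner_cluster(F: np.ndarray, clusters: Sequence[tuple[int, ClusterStats]]) -> int:
    """Id of the maximal-density cluster; ties broken by smallest id."""
    if len(clusters) == 0:
        raise ValueError("winner_cluster requires a non-empty cluster list")
    best_id, best_d = None, -1.0
    for cid, st in sorted(clusters, key=lambda c: c[0]):
        d = local_density(F, st)
        if d > best_d:
            best_id, best_d = cid, d
    return best_id


def cityblock(Q: np.ndarray, I: np.ndarray) -> float:
    """City-Block (Manhattan) distance: sum of absolute coordinate differences."""
    Q = np.asarray(Q, dtype=np.float64).ravel()
    I = np.asarray(I, dtype=np.float64).ravel()
    if Q.shape != I.shape:
        raise ValueError(f"dimension mismatch: {Q.shape[0]} vs {I.shape[0]}")
    return float(np.abs(Q - I).sum())


def rank_by_cityblock(
    Q: np.ndarray,
    candidates: Sequence[int],
    vectors: np.ndarray,
    top_n: int | None = None,
    query_id: object = None,
) -> RankedResult:
    """Rank candidate rows of ``vectors`` by City-Block distance to ``Q``.

    ``candidates`` are row indices doubling as item ids.  Ties by id.
    """
    Q = np.asarray(Q, dtype=np.float64).ravel()
    cand = sorted(int(c) for c in candidates)
    if not cand:
        return RankedResult(pairs=[], query_id=query_id)
    dists = np.abs(vectors[cand] - Q[None, :]).sum(axis=1)
    order = np.lexsort((np.asarray(cand), dists))
    pairs = [(cand[j], float(dists[j])) for j in order]
    if top_n is not None:
        pairs = pairs[:top_n]
    return RankedResult(pairs=pairs, query_id=query_id)


def descend(index, F: np.ndarray, beam: int = 1, trace: QueryTrace | None = None) -> list[int]:
    """Winner-takes-all descent; thin wrapper over the index method."""
    return index.descend(F, beam=beam, trace=trace)


def query(index, F: np.ndarray, top_n: int = 20, beam: int = 1):
    """Query the hierarchical index; thin wrapper over the index method."""
    return index.query(F, top_n=top_n, beam=beam, return_trace=True)
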