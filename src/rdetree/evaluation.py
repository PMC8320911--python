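"""Retrieval-quality metrics and the engine benchmark harness.

Average precision of one query's ranked list is

    AP = (1/R) * sum_k P(k) * rel(k)

where P(k) is the precision of the top-k results, rel(k) indicates whether
the k-th result is relevant, and R is the number of relevant items for the
query.  mAP averages AP over queries; P@N is the fraction of the top N
results sharing the query's class.  The benchmark runs engines over seeded
query sets on a labelled corpus and also accounts for work (density plus
distance evaluations per query), which is how the hierarchical engine's
speed-up over brute force is measured hardware-independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baselines import SequentialSearch
from .index import HierarchicalDensityIndex
from .search import RankedResult

__all__ = ["EvalReport", "precision_at_n", "average_precision",
           "mean_average_precision", "benchmark"]


@dataclass
class EvalReport:
    """Per-engine evaluation summary."""

    engine: str
    ap: list[float]
    p_at_n: dict[int, list[float]]
    eval_counts: list[int]
    metadata: dict = field(default_factory=dict)

    @property
    def map(self) -> float:
        return mean_average_precision(self.ap)

    def mean_p_at_n(self, N: int) -> float:
        return float(np.mean(self.p_at_n[N]))

    @property
    def mean_evals(self) -> float:
        return float(np.mean(self.eval_counts))

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "mAP": self.map,
            "P_at_N": {str(N): float(np.mean(v)) for N, v in self.p_at_n.items()},
            "mean_evaluations_per_query": self.mean_evals,
            "per_query_AP": [float(a) for a in self.ap],
            "metadata": self.metadata,
        }


def precision_at_n(ranked: RankedResult | Sequence, relevant: set, N: int) -> float:
    """|top-N intersect relevant| / N; short lists count missing slots as misses."""
    if N < 1:
        raise ValueError("N must be >= 1")
    ids = ranked.ids if isinstance(ranked, RankedResult) else [i for i, *_ in ranked]
    top = ids[:N]
    return sum(1 for i in top if i in relevant) / N


def average_precision(ranked: RankedResult | Sequence, relevant: set,
                      R: int | None = None, n: int | None = None) -> float:
    """Rank-weighted precision averaged over the relevant hits.

    ``R`` defaults to ``len(relevant)``; ``n`` truncates the retrieved
    list.  ``R`` must be positive — AP is undefined for a query with no
    relevant items.
    """
    ids = ranked.ids if isinstance(ranked, RankedResult) else [i for i, *_ in ranked]
    if R is None:
        R = len(relevant)
    if R < 1:
        raise ValueError("R (number of relevant items) must be >= 1")
    if n is not None:
        if n < 1:
            raise ValueError("n must be >= 1")
        ids = ids[:n]
    hits = 0
    total = 0.0
    for k, item in enumerate(ids, start=1):
        if item in relevant:
            hits += 1
            total += hits / k
    return total / R


def mean_average_precision(aps: Sequence[float]) -> float:
    if len(aps) == 0:
        raise ValueError("mAP requires at least one query")
    return float(np.mean(aps))


class _HierEngine:
    def __init__(self, index: HierarchicalDensityIndex, beam: int = 1):
        self.index, self.beam = index, beam

    def query(self, Q, top_n):
        result, trace = self.index.query(Q, top_n=top_n, beam=self.beam,
                                         return_trace=True)
        return result, trace.total_evals


class _SeqEngine:
    def __init__(self, X):
        self.engine = SequentialSearch().fit(X)

    def query(self, Q, top_n):
        return self.engine.query(Q, top_n=top_n)


def _make_engine(name: str, dataset, layer_sizes, beam, seed):
    if name in ("hier", "hierarchical"):
        idx = HierarchicalDensityIndex(layer_sizes=layer_sizes,
                                       random_state=seed).fit(dataset.features)
        return _HierEngine(idx, beam=beam)
    if name in ("seq", "sequential"):
        return _SeqEngine(dataset.features)
    raise ValueError(f"unknown engine name: {name!r}")


def benchmark(engines, dataset, query_ids: Sequence[int] | None = None,
              top_n: Sequence[int] = (20,), n_queries: int = 20,
              layer_sizes=None, beam: int = 1, seed: int = 0,
              exclude_self: bool = True) -> dict[str, EvalReport]:
    """Evaluate engines on a labelled feature set.

    ``engines`` is a list of names ("hier", "seq") and/or pre-built objects
    with a ``query(Q, top_n) -> (RankedResult, n_evals)`` method (supplied
    as (name, object) pairs).  Queries are indexed items: relevance is
    sharing the query's class label, and by default the query itself is
    excluded from both the ranked list and the relevant count R.
    ``query_ids`` defaults to ``n_queries`` items drawn without replacement
    with the given seed.
    """
    labels = np.asarray(dataset.labels)
    N = labels.shape[0]
    if query_ids is None:
        rng = np.random.default_rng(seed)
        query_ids = rng.choice(N, size=min(n_queries, N), replace=False)
    top_n = list(top_n)
    max_n = max(top_n)
    reports: dict[str, EvalReport] = {}
    for eng in engines:
        if isinstance(eng, str):
            name, obj = eng, _make_engine(eng, dataset, layer_sizes, beam, seed)
        else:
            name, obj = eng
        aps, counts = [], []
        p_table: dict[int, list[float]] = {Nv: [] for Nv in top_n}
        for q in query_ids:
            q = int(q)
            relevant = set(np.flatnonzero(labels == labels[q]).tolist())
            # AP is scored over the engine's full retrieved list (a beam-1
            # engine returns only the winning leaves' members); P@N over
            # its top-N prefix
            result, n_evals = obj.query(dataset.features[q], N)
            pairs = list(result.pairs)
            if exclude_self:
                relevant.discard(q)
                pairs = [(i, d) for i, d in pairs if i != q]
            ranked = RankedResult(pairs=pairs, query_id=q)
            aps.append(average_precision(ranked, relevant, R=len(relevant)))
            for Nv in top_n:
                p_table[Nv].append(precision_at_n(ranked, relevant, Nv))
            # the query's own self-comparison is not useful work
            counts.append(int(n_evals) - (1 if exclude_self else 0))
        reports[name] = EvalReport(
            engine=name, ap=aps, p_at_n=p_table, eval_counts=counts,
            metadata={"n_queries": len(query_ids), "top_n": top_n,
                      "seed": seed, "exclude_self": exclude_self,
                      "n_items": N},
        )
    return reports
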