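"""Hierarchically nested cluster index.

The index is a shallow tree built bottom-up by repeated K-means: the leaf
layer clusters the item feature vectors; each higher layer clusters the
*means* of the nodes one layer below.  Every node — leaf or internal —
carries the recursively maintainable statistics (mean ``mu``, mean squared
norm ``X``, count ``n``) over all item vectors beneath it, which is all the
density-guided query descent ever reads.

The estimator follows scikit-learn conventions: construct with
hyper-parameters, ``fit(X)`` to build, fitted attributes end in an
underscore, ``get_params``/``set_params`` work for grid search and cloning.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .search import QueryTrace, RankedResult, local_density, rank_by_cityblock
from .stats import ClusterStats, batch_stats, merge_stats, update_stats

__all__ = [
    "FormatError",
    "ClusterNode",
    "kmeans_layer",
    "HierarchicalDensityIndex",
    "build_index",
    "save_index",
    "load_index",
]

_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an index container is corrupt or version-mismatched."""


@dataclass
class ClusterNode:
    """One node of the hierarchy.

    Exactly one of ``members`` (leaf) / ``children`` (internal) is
    non-empty; ``stats`` always covers every item vector beneath the node.
    """

    id: int
    layer: int
    stats: ClusterStats
    members: list[int] = field(default_factory=list)
    children: list[int] = field(default_factory=list)
    parent: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.layer == 0


def kmeans_layer(points: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Hard K-means partition of ``points`` into at most ``k`` clusters.

    Uses k-means++ initialisation with a fixed seed (deterministic), at
    most 300 iterations, relative tolerance 1e-4.  Centers are recomputed
    as the exact means of the final assignment, so ``centers[j]`` equals
    the mean of the points labelled ``j``.  Labels of empty clusters do not
    occur in the output (callers may renumber).

    Raises
    ------
    ValueError
        If ``k`` exceeds the number of points or ``k < 1``.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n_points, got k={k}, n_points={n}")
    if k == n:
        return np.arange(n), points.copy()
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-4, random_state=seed)
    labels = km.fit_predict(points)
    centers = np.empty((k, points.shape[1]))
    for j in range(k):
        mask = labels == j
        centers[j] = points[mask].mean(axis=0) if mask.any() else km.cluster_centers_[j]
    return labels, centers


class HierarchicalDensityIndex(BaseEstimator):
    """Layered K-means index with density-guided approximate retrieval.

    Parameters
    ----------
    layer_sizes : sequence of int, optional
        Requested cluster counts per layer, bottom-up and strictly
        decreasing, e.g. ``[44, 10]``.  Defaults to the two-layer scheme
        ``[ceil(sqrt(N)), ceil(N**0.25)]`` at fit time.
    beam : int, default 1
        Number of clusters kept per layer during descent.  1 is strict
        winner-takes-all; larger values trade work for recall ("few
        winners take all").
    random_state : int, default 0
        Seed for every K-means run.
    drop_empty : bool, default True
        Drop clusters K-means left empty (realized layer size may shrink).
        If False, empty clusters are re-seeded on the farthest points.
    weighted_layers : bool, default False
        If True, higher layers cluster lower-layer means weighted by
        member count instead of the plain set of means.
    backfill : bool, default False
        If a query's winning leaves hold fewer than ``top_n`` items, expand
        to the next-best leaves by density instead of returning short.
    rebuild_factor : float, default 2.0
        Streaming inserts trigger a full rebuild once the item count
        exceeds this multiple of the count at the last build.
    """

    def __init__(self, layer_sizes=None, beam=1, random_state=0,
                 drop_empty=True, weighted_layers=False, backfill=False,
                 rebuild_factor=2.0):
        self.layer_sizes = layer_sizes
        self.beam = beam
        self.random_state = random_state
        self.drop_empty = drop_empty
        self.weighted_layers = weighted_layers
        self.backfill = backfill
        self.rebuild_factor = rebuild_factor

    # ------------------------------------------------------------------ build
    def fit(self, X, y=None):
        """Build the hierarchy over the rows of ``X`` (item ids = row indices)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("fit requires a non-empty 2-D feature matrix")
        n, dim = X.shape
        sizes = self._resolve_layer_sizes(n)
        self.dim_ = dim
        self.items_ = X.copy()
        self.ids_ = list(range(n))
        self._id_to_row = {i: i for i in self.ids_}
        self._build_tree(sizes)
        self._n_at_build = n
        return self

    def _resolve_layer_sizes(self, n: int) -> list[int]:
        if self.layer_sizes is None:
            sizes = [int(np.ceil(np.sqrt(n))), int(np.ceil(n ** 0.25))]
            sizes = [s for s in sizes if s >= 1]
            if len(sizes) == 2 and sizes[1] >= sizes[0]:
                sizes = sizes[:1]
        else:
            sizes = [int(s) for s in self.layer_sizes]
        if not sizes:
            raise ValueError("layer_sizes must be non-empty")
        if sizes[0] > n:
            raise ValueError(
                f"bottom layer size {sizes[0]} exceeds number of items {n}")
        if not all(sizes[i] > sizes[i + 1] for i in range(len(sizes) - 1)):
            raise ValueError(
                f"layer_sizes must be strictly decreasing bottom-up, got {sizes}")
        if any(s < 1 for s in sizes):
            raise ValueError(f"layer sizes must be positive, got {sizes}")
        return sizes

    def _build_tree(self, sizes: list[int]) -> None:
        X = self.items_
        rows = np.arange(X.shape[0])
        self.nodes_: dict[int, ClusterNode] = {}
        self.layers_: list[list[int]] = []
        next_id = 0

        # leaf layer over item vectors
        labels, _ = kmeans_layer(X, min(sizes[0], X.shape[0]), self.random_state)
        leaf_ids = []
        for lbl in np.unique(labels):
            members = [self.ids_[r] for r in rows[labels == lbl]]
            st = batch_stats(X[labels == lbl])
            node = ClusterNode(id=next_id, layer=0, stats=st, members=members)
            self.nodes_[next_id] = node
            leaf_ids.append(next_id)
            next_id += 1
        self.layers_.append(leaf_ids)

        # higher layers over the previous layer's node means
        for depth, k in enumerate(sizes[1:], start=1):
            prev = self.layers_[-1]
            means = np.array([self.nodes_[i].stats.mu for i in prev])
            if self.weighted_layers:
                w = np.array([self.nodes_[i].stats.n for i in prev], dtype=float)
                rep = np.repeat(np.arange(len(prev)), np.maximum(w.astype(int), 1))
                labels_rep, _ = kmeans_layer(means[rep], min(k, len(prev)),
                                             self.random_state + depth)
                labels = np.array([labels_rep[rep == j][0] for j in range(len(prev))])
            else:
                labels, _ = kmeans_layer(means, min(k, len(prev)),
                                         self.random_state + depth)
            layer_ids = []
            for lbl in np.unique(labels):
                child_ids = [prev[j] for j in np.flatnonzero(labels == lbl)]
                st = merge_stats([self.nodes_[c].stats for c in child_ids])
                node = ClusterNode(id=next_id, layer=depth, stats=st,
                                   children=child_ids)
                for c in child_ids:
                    self.nodes_[c].parent = next_id
                self.nodes_[next_id] = node
                layer_ids.append(next_id)
                next_id += 1
            self.layers_.append(layer_ids)

    # ------------------------------------------------------------------ query
    def descend(self, F, beam: int = 1, trace: QueryTrace | None = None) -> list[int]:
        """Top-down density descent; returns the surviving leaf ids (<= beam).

        At the top layer every node is scored; below, only children of the
        kept nodes are scored, keeping the ``beam`` densest per layer.  A
        beam wider than a layer is silently capped at the layer size.
        """
        self._check_fitted()
        F = self._check_vector(F)
        if beam < 1:
            raise ValueError("beam must be >= 1")
        frontier = list(self.layers_[-1])
        for depth in range(len(self.layers_) - 1, -1, -1):
            scored = []
            for nid in sorted(frontier):
                d = local_density(F, self.nodes_[nid].stats)
                scored.append((nid, d))
            if trace is not None:
                trace.evaluated.append(list(scored))
            # densest first; ties by smaller id (sorted order is stable)
            scored.sort(key=lambda t: (-t[1], t[0]))
            kept = [nid for nid, _ in scored[: min(beam, len(scored))]]
            if trace is not None:
                trace.kept.append(list(kept))
            if depth == 0:
                return kept
            frontier = [c for nid in kept for c in self.nodes_[nid].children]
        return kept

    def query(self, F, top_n: int = 20, beam: int | None = None,
              return_trace: bool = False):
        """Retrieve the ``top_n`` most similar items to ``F``.

        Candidates are the members of the leaves surviving the descent,
        ranked by City-Block distance ascending (ties by item id).  If the
        winning leaves hold fewer than ``top_n`` items the result is short,
        unless ``backfill`` expands to the next-densest leaves.
        """
        self._check_fitted()
        F = self._check_vector(F)
        if top_n < 1:
            raise ValueError("top_n must be >= 1")
        beam = self.beam if beam is None else beam
        trace = QueryTrace()
        leaves = self.descend(F, beam=beam, trace=trace)
        candidates = [m for lid in leaves for m in self.nodes_[lid].members]
        if self.backfill and len(candidates) < top_n:
            spare = [(lid, local_density(F, self.nodes_[lid].stats))
                     for lid in self.layers_[0] if lid not in set(leaves)]
            spare.sort(key=lambda t: (-t[1], t[0]))
            for lid, d in spare:
                trace.evaluated[-1].append((lid, d))
                candidates.extend(self.nodes_[lid].members)
                if len(candidates) >= top_n:
                    break
        rows = [self._id_to_row[c] for c in candidates]
        dmat = np.abs(self.items_[rows] - F[None, :]).sum(axis=1)
        trace.n_distance_evals = len(candidates)
        order = np.lexsort((np.asarray(candidates), dmat))
        pairs = [(candidates[j], float(dmat[j])) for j in order][:top_n]
        result = RankedResult(pairs=pairs)
        return (result, trace) if return_trace else result

    # ----------------------------------------------------------------- insert
    def insert(self, F, item_id: int):
        """Stream one new item into the index.

        The item is routed by beam-1 density descent to a leaf; the leaf's
        membership is extended and its statistics — and those of every
        ancestor — are updated by the one-sample recursion, so node stats
        stay exactly the batch stats of their members.  Once the item count
        exceeds ``rebuild_factor`` times the count at the last build, the
        whole hierarchy is rebuilt.
        """
        self._check_fitted()
        F = self._check_vector(F)
        item_id = int(item_id)
        if item_id in self._id_to_row:
            raise ValueError(f"item id {item_id} is already indexed")
        leaf_id = self.descend(F, beam=1)[0]
        self.items_ = np.vstack([self.items_, F[None, :]])
        self._id_to_row[item_id] = self.items_.shape[0] - 1
        self.ids_.append(item_id)
        node = self.nodes_[leaf_id]
        node.members.append(item_id)
        while node is not None:
            node.stats = update_stats(node.stats, F)
            node = self.nodes_[node.parent] if node.parent is not None else None
        if self.items_.shape[0] > self.rebuild_factor * self._n_at_build:
            sizes = [len(l) for l in self.layers_]
            order = np.argsort(self.ids_)
            self.items_ = self.items_[order]
            self.ids_ = [self.ids_[j] for j in order]
            self._id_to_row = {i: r for r, i in enumerate(self.ids_)}
            self._build_tree(sizes)
            self._n_at_build = self.items_.shape[0]
        return self

    # ------------------------------------------------------------------ misc
    @property
    def n_items_(self) -> int:
        return self.items_.shape[0]

    def leaf_of(self, item_id: int) -> int:
        for lid in self.layers_[0]:
            if item_id in self.nodes_[lid].members:
                return lid
        raise KeyError(item_id)

    def _check_fitted(self) -> None:
        if not hasattr(self, "nodes_"):
            raise ValueError("index is not fitted; call fit(X) first")

    def _check_vector(self, F) -> np.ndarray:
        F = np.asarray(F, dtype=np.float64).ravel()
        if F.shape[0] != self.dim_:
            raise ValueError(
                f"dimension mismatch: index dim {self.dim_}, vector dim {F.shape[0]}")
        return F

    def structurally_equal(self, other: "HierarchicalDensityIndex") -> bool:
        """Full-precision equality of items, topology, and statistics."""
        if (self.dim_ != other.dim_ or self.ids_ != other.ids_
                or [sorted(l) for l in self.layers_] != [sorted(l) for l in other.layers_]):
            return False
        if not np.array_equal(self.items_, other.items_):
            return False
        for nid, node in self.nodes_.items():
            o = other.nodes_.get(nid)
            if o is None or node.layer != o.layer or node.parent != o.parent:
                return False
            if sorted(node.members) != sorted(o.members):
                return False
            if sorted(node.children) != sorted(o.children):
                return False
            if (node.stats.n != o.stats.n
                    or not np.array_equal(node.stats.mu, o.stats.mu)
                    or node.stats.X != o.stats.X):
                return False
        return True

    # ------------------------------------------------------------- container
    def save(self, path) -> None:
        """Write the index container: zip of JSON manifest + LE float64 arrays."""
        self._check_fitted()
        manifest = {
            "format_version": _FORMAT_VERSION,
            "dim": self.dim_,
            "layer_sizes": [len(l) for l in self.layers_],
            "random_state": self.random_state,
            "params": {k: v for k, v in self.get_params().items()
                       if k != "layer_sizes"},
            "requested_layer_sizes": list(self.layer_sizes) if self.layer_sizes else None,
            "n_items": self.n_items_,
            "n_at_build": self._n_at_build,
            "ids": self.ids_,
            "nodes": [
                {
                    "id": n.id, "layer": n.layer, "parent": n.parent,
                    "members": n.members, "children": n.children,
                    "n": n.stats.n,
                }
                for n in (self.nodes_[i] for layer in self.layers_ for i in layer)
            ],
        }
        node_order = [n["id"] for n in manifest["nodes"]]
        means = np.array([self.nodes_[i].stats.mu for i in node_order])
        xs = np.array([self.nodes_[i].stats.X for i in node_order])
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("manifest.json", json.dumps(manifest))
            zf.writestr("items.bin", self.items_.astype("<f8").tobytes())
            zf.writestr("node_means.bin", means.astype("<f8").tobytes())
            zf.writestr("node_X.bin", xs.astype("<f8").tobytes())

    @classmethod
    def load(cls, path) -> "HierarchicalDensityIndex":
        """Read an index container; lossless inverse of :meth:`save`."""
        try:
            with zipfile.ZipFile(path) as zf:
                manifest = json.loads(zf.read("manifest.json"))
                items_raw = zf.read("items.bin")
                means_raw = zf.read("node_means.bin")
                xs_raw = zf.read("node_X.bin")
        except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError) as e:
            raise FormatError(
                f"corrupt index container (expected format version {_FORMAT_VERSION}): {e}"
            ) from e
        if manifest.get("format_version") != _FORMAT_VERSION:
            raise FormatError(
                f"index container version {manifest.get('format_version')!r}; "
                f"expected {_FORMAT_VERSION}")
        dim = manifest["dim"]
        n_items = manifest["n_items"]
        items = np.frombuffer(items_raw, dtype="<f8")
        if items.size != n_items * dim:
            raise FormatError(
                f"item array holds {items.size} values, manifest declares "
                f"{n_items}x{dim}")
        nodes_meta = manifest["nodes"]
        means = np.frombuffer(means_raw, dtype="<f8")
        xs = np.frombuffer(xs_raw, dtype="<f8")
        if means.size != len(nodes_meta) * dim or xs.size != len(nodes_meta):
            raise FormatError("node statistic arrays inconsistent with manifest")
        obj = cls(**manifest["params"],
                  layer_sizes=manifest["requested_layer_sizes"])
        obj.dim_ = dim
        obj.items_ = items.reshape(n_items, dim).astype(np.float64).copy()
        obj.ids_ = [int(i) for i in manifest["ids"]]
        obj._id_to_row = {i: r for r, i in enumerate(obj.ids_)}
        obj._n_at_build = manifest["n_at_build"]
        means = means.reshape(len(nodes_meta), dim)
        obj.nodes_ = {}
        n_layers = len(manifest["layer_sizes"])
        obj.layers_ = [[] for _ in range(n_layers)]
        for j, meta in enumerate(nodes_meta):
            st = ClusterStats(mu=means[j].copy(), X=float(xs[j]), n=int(meta["n"]))
            node = ClusterNode(id=int(meta["id"]), layer=int(meta["layer"]),
                               stats=st,
                               members=[int(m) for m in meta["members"]],
                               children=[int(c) for c in meta["children"]],
                               parent=meta["parent"])
            obj.nodes_[node.id] = node
            obj.layers_[node.layer].append(node.id)
        return obj


# ------------------------------------------------------------ thin wrappers

def build_index(features, layer_sizes, seed: int = 0,
                **kwargs) -> HierarchicalDensityIndex:
    """Build a :class:`HierarchicalDensityIndex` over a feature matrix or
    a labelled feature set (anything with a ``.features`` attribute)."""
    X = getattr(features, "features", features)
    return HierarchicalDensityIndex(layer_sizes=layer_sizes, random_state=seed,
                                    **kwargs).fit(X)


def save_index(index: HierarchicalDensityIndex, path) -> None:
    index.save(path)


def load_index(path) -> HierarchicalDensityIndex:
    return HierarchicalDensityIndex.load(path)
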