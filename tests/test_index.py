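"""Hierarchy construction, streaming insert, and the index container."""

import numpy as np
import pytest

from rdetree import (HierarchicalDensityIndex, FormatError, batch_stats,
                     build_index, gaussian_mixture_features, kmeans_layer,
                     merge_stats)


class TestKmeansLayer:
    def test_saturated_k_gives_singletons(self):
        pts = np.array([[0.0], [1.0], [5.0]])
        labels, centers = kmeans_layer(pts, k=3, seed=0)
        assert sorted(labels.tolist()) == [0, 1, 2]
        assert np.allclose(np.sort(centers.ravel()), [0, 1, 5])

    def test_two_tight_groups(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels, centers = kmeans_layer(pts, k=2, seed=0)
        assert labels[0] == labels[1] != labels[2] == labels[3]
        assert np.allclose(np.sort(centers.ravel()), [0.05, 10.05])

    def test_k1_center_is_global_mean(self, rng):
        pts = rng.normal(size=(30, 4))
        _, centers = kmeans_layer(pts, k=1, seed=0)
        assert np.allclose(centers[0], pts.mean(axis=0))

    def test_centers_are_assignment_means(self, rng):
        pts = rng.normal(size=(60, 3))
        labels, centers = kmeans_layer(pts, k=4, seed=1)
        for j in np.unique(labels):
            assert np.allclose(centers[j], pts[labels == j].mean(axis=0))

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(50, 5))
        a = kmeans_layer(pts, 5, seed=3)
        b = kmeans_layer(pts, 5, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_layer(np.zeros((3, 2)), k=4, seed=0)


class TestBuild:
    def test_four_corner_groups(self):
        rng = np.random.default_rng(0)
        corners = np.array([[0, 0], [0, 10], [10, 0], [10, 10]], dtype=float)
        X = np.vstack([c + 0.1 * rng.standard_normal((10, 2)) for c in corners])
        labels = np.repeat(np.arange(4), 10)
        idx = HierarchicalDensityIndex(layer_sizes=[4, 2], random_state=0).fit(X)
        assert len(idx.layers_[0]) == 4 and len(idx.layers_[1]) == 2
        # each leaf pure, each root covers 2 leaves
        for lid in idx.layers_[0]:
            mem_labels = labels[idx.nodes_[lid].members]
            assert len(set(mem_labels.tolist())) == 1
        assert sorted(len(idx.nodes_[r].children) for r in idx.layers_[1]) == [2, 2]

    def test_single_leaf_degenerate(self, rng):
        X = rng.normal(size=(12, 3))
        idx = HierarchicalDensityIndex(layer_sizes=[1], random_state=0).fit(X)
        node = idx.nodes_[idx.layers_[0][0]]
        assert sorted(node.members) == list(range(12))
        assert node.stats.allclose(batch_stats(X))

    def test_partition_property(self, leaf_index, leaf_corpus):
        seen = [m for lid in leaf_index.layers_[0]
                for m in leaf_index.nodes_[lid].members]
        assert sorted(seen) == list(range(leaf_corpus.n_items))

    def test_leaf_class_purity(self, leaf_index, leaf_corpus):
        # on a well-separated 44-class corpus every leaf is >= 90% one class
        labels = leaf_corpus.labels
        for lid in leaf_index.layers_[0]:
            mem = leaf_index.nodes_[lid].members
            counts = np.bincount(labels[mem])
            assert counts.max() / len(mem) >= 0.90

    def test_internal_stats_match_descendant_batch(self, leaf_index, leaf_corpus):
        X = leaf_corpus.features
        for nid in leaf_index.layers_[1]:
            node = leaf_index.nodes_[nid]
            members = [m for c in node.children
                       for m in leaf_index.nodes_[c].members]
            assert node.stats.allclose(batch_stats(X[members]), rtol=1e-9)
            kids = merge_stats([leaf_index.nodes_[c].stats for c in node.children])
            assert node.stats.allclose(kids, rtol=1e-9)

    def test_infeasible_layer_sizes_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            HierarchicalDensityIndex(layer_sizes=[50]).fit(X)
        with pytest.raises(ValueError):
            HierarchicalDensityIndex(layer_sizes=[4, 6]).fit(X)
        with pytest.raises(ValueError):
            HierarchicalDensityIndex(layer_sizes=[]).fit(X)
        with pytest.raises(ValueError):
            HierarchicalDensityIndex().fit(np.empty((0, 4)))

    def test_default_layer_sizes(self, rng):
        X = rng.normal(size=(100, 4))
        idx = HierarchicalDensityIndex(random_state=0).fit(X)
        assert len(idx.layers_) == 2
        assert len(idx.layers_[0]) <= 10  # ceil(sqrt(100))

    def test_build_index_wrapper_accepts_feature_set(self, small_mixture):
        idx = build_index(small_mixture, layer_sizes=[5, 2], seed=0)
        assert idx.n_items_ == small_mixture.n_items


class TestInsert:
    def test_insert_updates_stats_to_batch(self, rng):
        X = rng.normal(size=(8, 3))
        idx = HierarchicalDensityIndex(layer_sizes=[1], random_state=0).fit(X)
        new = rng.normal(size=3)
        idx.insert(new, 8)
        node = idx.nodes_[idx.layers_[0][0]]
        assert node.stats.allclose(batch_stats(np.vstack([X, new])), rtol=1e-9)

    def test_insert_at_leaf_mean_routes_there(self, small_mixture):
        idx = HierarchicalDensityIndex(layer_sizes=[5, 2], random_state=0,
                                       rebuild_factor=10).fit(small_mixture.features)
        lid = idx.layers_[0][2]
        mu = idx.nodes_[lid].stats.mu.copy()
        idx.insert(mu, 10_000)
        assert 10_000 in idx.nodes_[lid].members

    def test_streamed_inserts_match_batch_stats(self, rng):
        # route 100 extra items; every touched node's stats must equal the
        # batch stats over its own members
        base = gaussian_mixture_features(C=4, M=20, K=6, s=6, seed=5)
        idx = HierarchicalDensityIndex(layer_sizes=[4, 2], random_state=0,
                                       rebuild_factor=100).fit(base.features)
        extra = gaussian_mixture_features(C=4, M=25, K=6, s=6, seed=5)
        for j, v in enumerate(extra.features):
            idx.insert(v + 0.01, 1000 + j)
        for lid in idx.layers_[0]:
            node = idx.nodes_[lid]
            vecs = idx.items_[[idx._id_to_row[m] for m in node.members]]
            assert node.stats.allclose(batch_stats(vecs), rtol=1e-9)
        for nid in idx.layers_[1]:
            node = idx.nodes_[nid]
            members = [m for c in node.children for m in idx.nodes_[c].members]
            vecs = idx.items_[[idx._id_to_row[m] for m in members]]
            assert node.stats.allclose(batch_stats(vecs), rtol=1e-9)

    def test_duplicate_id_rejected(self, small_mixture):
        idx = HierarchicalDensityIndex(layer_sizes=[5]).fit(small_mixture.features)
        with pytest.raises(ValueError, match="already indexed"):
            idx.insert(small_mixture.features[0], 0)

    def test_growth_triggers_rebuild(self, rng):
        X = rng.normal(size=(10, 2))
        idx = HierarchicalDensityIndex(layer_sizes=[2], random_state=0,
                                       rebuild_factor=1.5).fit(X)
        for j in range(8):
            idx.insert(rng.normal(size=2), 100 + j)
        assert idx._n_at_build > 10  # a rebuild happened
        seen = [m for lid in idx.layers_[0] for m in idx.nodes_[lid].members]
        assert len(seen) == 18 and len(set(seen)) == 18


class TestContainer:
    def test_round_trip_equality(self, leaf_index, tmp_path):
        p = tmp_path / "idx.zip"
        leaf_index.save(p)
        loaded = HierarchicalDensityIndex.load(p)
        assert leaf_index.structurally_equal(loaded)

    def test_round_trip_after_insert(self, small_mixture, tmp_path):
        idx = HierarchicalDensityIndex(layer_sizes=[5, 2], random_state=0,
                                       rebuild_factor=10).fit(small_mixture.features)
        idx.insert(np.zeros(small_mixture.dim), 999)
        p = tmp_path / "idx.zip"
        idx.save(p)
        assert idx.structurally_equal(HierarchicalDensityIndex.load(p))

    def test_truncated_container_rejected(self, leaf_index, tmp_path):
        p = tmp_path / "idx.zip"
        leaf_index.save(p)
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 2])
        with pytest.raises(FormatError):
            HierarchicalDensityIndex.load(p)

    def test_manifest_dim_mismatch_rejected(self, small_mixture, tmp_path):
        import json
        import zipfile

        idx = HierarchicalDensityIndex(layer_sizes=[3]).fit(small_mixture.features)
        p = tmp_path / "idx.zip"
        idx.save(p)
        with zipfile.ZipFile(p) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            payload = {n: zf.read(n) for n in zf.namelist()}
        manifest["dim"] = manifest["dim"] + 1
        payload["manifest.json"] = json.dumps(manifest).encode()
        with zipfile.ZipFile(p, "w") as zf:
            for name, blob in payload.items():
                zf.writestr(name, blob)
        with pytest.raises(FormatError, match="manifest"):
            HierarchicalDensityIndex.load(p)

    def test_loaded_index_answers_queries(self, leaf_index, leaf_corpus, tmp_path):
        p = tmp_path / "idx.zip"
        leaf_index.save(p)
        loaded = HierarchicalDensityIndex.load(p)
        q = leaf_corpus.features[17]
        a = leaf_index.query(q, top_n=10)
        b = loaded.query(q, top_n=10)
        assert a.pairs == b.pairs
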