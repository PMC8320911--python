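"""Reference competitors: exhaustive sequential search and a simplified
bag-of-visual-words inverted index.

``SequentialSearch`` is the exactness oracle for every approximate path:
it scores the query against every indexed vector (exactly N City-Block
evaluations) and sorts.  ``InvertedWordIndex`` quantizes local descriptors
against a K-means codebook, keeps word -> image posting lists, pre-filters
candidates by shared-word count, and re-ranks candidates by City-Block
distance over their word-count histograms.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .index import kmeans_layer
from .search import RankedResult

__all__ = ["SequentialSearch", "InvertedWordIndex",
           "sequential_search", "build_inverted_index", "inverted_query"]


class SequentialSearch(BaseEstimator):
    """Brute-force City-Block scan over all indexed vectors."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("fit requires a non-empty 2-D feature matrix")
        self.items_ = X.copy()
        self.dim_ = X.shape[1]
        return self

    def query(self, Q, top_n: int | None = None):
        """Rank every item by City-Block distance; returns (result, n_evals)."""
        Q = np.asarray(Q, dtype=np.float64).ravel()
        if Q.shape[0] != self.dim_:
            raise ValueError(
                f"dimension mismatch: index dim {self.dim_}, query dim {Q.shape[0]}")
        # same summation order as the hierarchical re-ranking stage, so the
        # full-beam equivalence with the tree search is bit-exact
        d = np.abs(self.items_ - Q[None, :]).sum(axis=1)
        ids = np.arange(self.items_.shape[0])
        order = np.lexsort((ids, d))
        pairs = [(int(i), float(d[i])) for i in order]
        if top_n is not None:
            pairs = pairs[:top_n]
        return RankedResult(pairs=pairs), self.items_.shape[0]


def sequential_search(features: np.ndarray, Q, top_n: int | None = None) -> RankedResult:
    """Functional form of :class:`SequentialSearch` (ids = row indices)."""
    result, _ = SequentialSearch().fit(features).query(Q, top_n=top_n)
    return result


class InvertedWordIndex(BaseEstimator):
    """Visual-word inverted index over per-image local descriptor sets.

    Parameters
    ----------
    n_words : int, default 16
        Codebook (vocabulary) size W.
    min_shared : int, default 1
        Candidate filter: images must share at least this many distinct
        words with the query.  The weakest useful filter (1) is the
        default; stricter values shrink the candidate set monotonically.
    random_state : int, default 0
        Codebook K-means seed.
    """

    def __init__(self, n_words: int = 16, min_shared: int = 1, random_state: int = 0):
        self.n_words = n_words
        self.min_shared = min_shared
        self.random_state = random_state

    def fit(self, descriptor_sets, y=None):
        """Learn the codebook over pooled descriptors and build postings.

        ``descriptor_sets`` is a list (one per image) of (m_i, d) arrays.
        """
        sets = [np.asarray(s, dtype=np.float64) for s in descriptor_sets]
        pooled = np.vstack(sets)
        if pooled.shape[0] < self.n_words:
            raise ValueError(
                f"vocabulary size {self.n_words} exceeds descriptor count "
                f"{pooled.shape[0]}")
        _, centers = kmeans_layer(pooled, self.n_words, self.random_state)
        self.codebook_ = centers
        W = centers.shape[0]
        self.histograms_ = np.zeros((len(sets), W))
        self.postings_ = {w: [] for w in range(W)}
        for img_id, s in enumerate(sets):
            words = self._assign(s)
            counts = np.bincount(words, minlength=W)
            self.histograms_[img_id] = counts
            for w in np.flatnonzero(counts):
                self.postings_[int(w)].append((img_id, int(counts[w])))
        return self

    def _assign(self, descriptors: np.ndarray) -> np.ndarray:
        d = cdist(descriptors, self.codebook_)
        return d.argmin(axis=1)

    def query(self, query_descriptors, top_n: int | None = None,
              min_shared: int | None = None):
        """Candidate pre-filter by shared words, histogram re-rank.

        Returns ``(RankedResult, n_candidate_evaluations)``.  Sharing fewer
        than ``min_shared`` distinct words with every image yields an empty
        result, not an error.
        """
        t = self.min_shared if min_shared is None else min_shared
        if t < 1:
            raise ValueError("min_shared must be >= 1")
        qd = np.asarray(query_descriptors, dtype=np.float64)
        words = self._assign(qd)
        W = self.codebook_.shape[0]
        q_hist = np.bincount(words, minlength=W).astype(np.float64)
        shared = {}
        for w in set(int(w) for w in words):
            for img_id, _ in self.postings_[w]:
                shared[img_id] = shared.get(img_id, 0) + 1
        cand = sorted(i for i, c in shared.items() if c >= t)
        if not cand:
            return RankedResult(pairs=[]), 0
        d = np.abs(self.histograms_[cand] - q_hist[None, :]).sum(axis=1)
        order = np.lexsort((np.asarray(cand), d))
        pairs = [(cand[j], float(d[j])) for j in order]
        if top_n is not None:
            pairs = pairs[:top_n]
        return RankedResult(pairs=pairs), len(cand)


def build_inverted_index(local_descriptor_sets, W: int, seed: int = 0) -> InvertedWordIndex:
    return InvertedWordIndex(n_words=W, random_state=seed).fit(local_descriptor_sets)


def inverted_query(inv: InvertedWordIndex, query_descriptors,
                   min_shared: int = 1, top_n: int | None = None) -> RankedResult:
    result, _ = inv.query(query_descriptors, top_n=top_n, min_shared=min_shared)
    return result
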