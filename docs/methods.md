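# Methods

## The retrieval model

Each image is represented by one fixed-length real vector **F** (any
extractor that yields a dense vector works; the package's default toy
extractor produces per-channel grid-block means, and the optional deep
adapter produces the 2048-D global-pooled penultimate activations of a
50-layer residual network pretrained on ImageNet).

The collection is indexed as a shallow tree of clusters built bottom-up:

1. **Leaf layer** — K-means over the item vectors (k-means++
   initialisation, ≤300 iterations, relative tolerance 1e-4, fixed seed;
   centers are recomputed as exact assignment means after convergence so
   every reported center is the mean of its assigned points).
2. **Higher layers** — K-means over the *means* of the nodes one layer
   below.  An optional flag clusters means weighted by member count
   instead; the unweighted reading is the default because the higher
   layers are meant to summarise cluster geometry, not occupancy.

Every node stores only `(µ, X, n)`: the mean of all item vectors beneath
it, the mean of their squared norms, and their count.  Both admit the
exact one-sample recursion

    µ_i = (i−1)/i µ_{i−1} + F_i/i,   X_i = (i−1)/i X_{i−1} + ‖F_i‖²/i

with base case `µ_1 = F_1`, `X_1 = ‖F_1‖²`.  Internal-node statistics are
the count-weighted merge of their children's, which is algebraically
identical to the batch statistics over all descendant members.  The
recursion is order-invariant up to round-off; the suite checks agreement
with the batch closure at 1e-9 relative tolerance.

### Query descent

The local density of a query w.r.t. a cluster is a Cauchy-type kernel
evaluated from the sufficient statistics alone:

    D_c = 1 / (1 + ‖F − µ_c‖² + X_c − ‖µ_c‖²)

The distance is squared Euclidean — required for the identity that makes
the variance term recursively maintainable.  `X − ‖µ‖²` is non-negative in
exact arithmetic; the implementation clamps the denominator at 1 so
round-off can never push a density above 1.  D lies in (0, 1], equals 1
exactly on a singleton cluster queried at its own member, and is strictly
decreasing in query-to-mean distance for fixed statistics.

Search evaluates D over all top-layer nodes, keeps the `beam` densest
(per-layer top-m, not global; default beam 1 = strict winner-takes-all),
and recurses over their children only.  Ties in density, and ties in the
final distance ranking, break toward the smaller id so output is
deterministic across platforms.  A beam wider than a layer is silently
capped.  Members of the surviving leaves are ranked by City-Block
distance, ascending.  If the winning leaves hold fewer than `top_n` items
the result is returned short — that is the method's own semantics; an
optional `backfill` flag expands to the next-densest leaves, which is the
natural remedy for near-border queries.

### Streaming inserts

An insert routes the new vector by beam-1 descent to a leaf, appends it,
and folds it into the statistics of the leaf and every ancestor, so node
statistics remain exactly the batch statistics of their members.  Because
the tree topology itself is frozen between builds, drift accumulates as
the collection grows; a rebuild triggers automatically once the item count
exceeds `rebuild_factor` (default 2.0) times the count at the last build.

## Baselines and metrics

`SequentialSearch` scores the query against every indexed vector (exactly
N City-Block evaluations) and is the exactness oracle: with the beam
covering every leaf, the hierarchical query provably degenerates to it,
and the suite asserts bit-exact agreement of the ranked lists (both paths
use the same summation order).

`InvertedWordIndex` is a deliberately simplified bag-of-visual-words
competitor: a K-means codebook over pooled local descriptors, word→image
posting lists, candidate pre-filtering by shared distinct-word count
(threshold default 1 — the weakest useful filter; stricter thresholds
shrink candidate sets monotonically) and City-Block re-ranking over
word-count histograms.  It exists for comparison-count accounting, not as
a faithful SIFT/LLC/SPM reproduction; the descriptor-length arithmetic for
a three-level spatial pyramid ((1+4+16)·K bins) is provided separately.

Metrics: AP = Σ_k P(k)·rel(k) / R over a query's ranked list, mAP the mean
over queries, P@N the top-N precision.  The benchmark treats queries as
indexed items and excludes the self-match from both the ranked list and R
(so R defaults to class size − 1); AP is scored over the engine's full
retrieved list — a beam-1 engine returns only the winning leaves' members
— while P@N uses the top-N prefix.  Work is compared by counting density
plus distance evaluations per query from the recorded `QueryTrace`, never
by wall-clock, so the speed-up claim is hardware-independent.

## Synthetic corpus

`gaussian_mixture_features(C, M, K, s, sigma, seed)` emulates a labelled
image collection: class means uniform on the sphere of radius
`s·sigma·√K`, items = mean + isotropic N(0, σ²) noise.  The separation
`s` reads as mean distance from the origin in per-axis noise units; the
default `s = 6` models well-separated classes, and the suite's standard
corpus is 44 classes × 52 items at K = 64 with a [44, 10] hierarchy —
the shape of a mid-sized leaf-species collection, with layer sizes equal
to class count and roughly its square root.  Benchmarks use 100 seeded
in-corpus queries (20 for the smaller paired-engine checks), sizes chosen
so the whole suite runs in seconds at desk scale.  Randomness is split
per class through seed substreams, so generating more classes never
perturbs earlier classes' draws.  `synthetic_images` adds deterministic
per-class stripe/checker patterns with pixel noise for exercising the
extractors.

What the generator does *not* model: photographic nuisance factors
(illumination, pose, occlusion), heavy-tailed or correlated feature noise,
unbalanced classes, and the cluster overlap of hard real corpora.  Passing
tests therefore demonstrate the correctness of the machinery and its
behaviour on separable data, not real-world retrieval accuracy; on real
collections the beam-1 descent is an approximation and can miss the true
nearest neighbour near cluster borders (the `beam` and `backfill` knobs
exist precisely for that regime).

## Numerical and design choices

- All statistics in float64; container arrays serialized little-endian
  float64 inside a single zip archive with a JSON manifest (format
  version, dims, node table); loading validates version and array sizes
  and refuses partial indexes.
- Empty K-means clusters are dropped, so a layer's realized size may be
  smaller than requested.
- Layer sizes are pure configuration (default two layers,
  ⌈√N⌉ / ⌈N^¼⌉); nothing is inferred from labels.
- The deep adapter defaults to the 50-layer residual variant — the
  smallest with a 2048-D penultimate layer — and applies no feature
  normalisation by default; bilinear resize to 224×224.
- `ClusterStats` is immutable; updates return new values, which keeps the
  recursion testable against the batch oracle.

## Known limitations

- The index stores all item vectors (needed for re-ranking); only the
  *density* stage is memory-light.
- Inserts do not split or merge clusters; quality between rebuilds
  degrades if the data distribution drifts.
- The inverted-index baseline quantizes with a toy codebook and toy
  descriptors; its absolute numbers are not comparable to full
  SIFT-based systems.
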