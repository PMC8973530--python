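# Methods

## Model and assumptions

`wordmanifold` treats a pre-trained word embedding as a noisy sample from a
low-dimensional manifold embedded in the ambient vector space, and replaces
ambient coordinates with manifold-adapted ones. Three assumptions carry the
whole construction:

1. **Locality.** Each word's semantic neighborhood is well approximated by
   an affine combination of its k nearest neighbors *on the manifold*.
2. **Frequency coverage.** The most frequent words sample the manifold
   densely enough that a window of the frequency ranking (default the top
   1001 words) supports the local fits; the rest of the vocabulary can be
   attached out of sample.
3. **Graph-geodesic fidelity.** Shortest paths on a k-NN graph approximate
   geodesic distances along the manifold, which presumes neighborhoods do
   not "short-circuit" across folds of the surface.

The learner is Modified LLE: each training point contributes `s_i`
linearly independent sum-to-one weight vectors built from the regularized
barycentric solution plus the trailing singular subspace of its local Gram
matrix, rotated by a Householder reflection so the affine constraint is
preserved. Using multiple weights per point removes the instability of
classical LLE when the local Gram matrix is rank deficient — which is the
generic case here, because word neighborhoods (k up to several hundred)
usually exceed the local intrinsic dimension.

Neighborhoods themselves are chosen by the normalized geodesic metric
`d_ij = f(x_i,x_j)/sqrt(d(x_i)·d(x_j))`: geodesics replace straight lines,
and the normalization by each point's mean geodesic distance makes the
selection scale-free, so dense and sparse regions of the vocabulary get
comparable neighborhoods. Selection is two-stage — a Euclidean k-NN graph
defines the geodesics, the normalized metric then picks the final neighbor
sets — since geodesics cannot exist before some graph does.

## Parameters

| parameter | default | meaning and guidance |
|---|---|---|
| `window_start`, `window_size` | 0, 1001 | frequency window; starts at the most frequent word. Window sizes of 1001–2001 are the intended operating range; the O(n²) distance matrices stay below ~35 MB. |
| `k` (`--neighbors`) | 500 | MLLE neighborhood size. The method tolerates `k ≤ d` (each point then contributes one weight vector and the fit degenerates towards regularized LLE — logged); `k` in the hundreds against windows of ~1000–2000 matches the intended regime. |
| `d` (`--dim`) | input dimension D | embedding dimension. The default re-embeds between equally-dimensional spaces (no reduction); information is lost when `d < D` is forced. Requires `d ≤ n−2`. |
| `k_graph` | `k` | neighbor count of the geodesic graph. |
| `gamma_scale` | 1e-3 | regularization of the local weight solve, `γ = gamma_scale · trace(G_i)` (unitless, relative to the local scale). Conditions rank-deficient neighborhoods; see "Numerical choices" for its bias. |
| `eta` | `"median"` | split threshold between "large" and "small" local singular values. The adaptive default takes the median over points of the tail-to-head energy ratio at dimension d, the published MLLE criterion; a fixed float is accepted. `s_i` is clamped to `[1, k−d]`. |
| `k_oos` | `k` | out-of-sample neighborhood size. |
| `oov_policy` | `skip` | evaluation treatment of unresolvable terms: skipping reports honest coverage; `random_seeded` (uniform components in `[−0.5/D, 0.5/D]`, deterministic per word and seed) matches the convention of downstream task training. |

## Out-of-sample extension

A new vector is attached by Euclidean k-NN against the training window (a
novel point has no graph edges, so Euclidean attachment is the minimal
choice; an experimental flag ranks neighbors by graph-attached geodesics
instead). Its sum-to-one regularized weights reproduce the training rule,
and `y = Σ w_j y_j` is the closed-form minimizer of the single-point
embedding cost. The map is exactly linear in `Y_train` and
translation-equivariant; training points re-enter within a fraction of a
percent of the embedding scale.

`reembed_vocabulary` passes training-window words through to their fitted
coordinates by default (exact idempotence on the window). For evaluation
experiments the package re-transforms *all* words
(`reuse_training=False`): the re-embedding algorithm applies the same
out-of-sample map to every vocabulary word, and mixing raw eigenvector
coordinates (which carry high-order harmonics of the manifold) with
transformed ones produces an inconsistent space — the transform's
neighborhood averaging acts as a low-pass filter, and applying it uniformly
is both the faithful reading of the re-embedding procedure and measurably
better behaved under cosine evaluation.

## Synthetic data: what it emulates, and what not

The generator produces vocabularies near a swiss roll, S-curve or linear
subspace, lifted into the ambient dimension by a random orthogonal map
(norm-preserving, so the noise scale is interpretable across dimensions)
with isotropic Gaussian noise. Both curved surfaces are arc-length
parametrized, so Euclidean distance in latent coordinates equals geodesic
distance along the surface; gold similarity ratings
`10·exp(−dist/τ)` (τ = median sampled distance) are therefore genuinely
monotone in geodesic proximity. Pair sampling is stratified across the
latent distance range, emulating how human similarity benchmarks are
constructed to span their rating scale — uniform random pairs of a large
vocabulary would be almost all unrelated, with near-tied ratings that carry
no rank information. Zipfian counts emulate the frequency side file.

What passing tests on these fixtures shows: the geometry pipeline
(neighborhoods → weights → eigenproblem → out-of-sample map) behaves as
specified, and re-embedding recovers geodesic structure that ambient cosine
distorts. What it does not show: anything about real clinical language —
true word vectors have unknown intrinsic dimension, anisotropic frequency
effects, polysemy, and no ground-truth geodesic; improvements on UMNSRS-
or MayoSRS-style data must be measured on that data.

The benchmark defaults (1500 words, D=100, noise 0.05, window 1000, k=100,
d=100, 300 pairs) keep the full pipeline — including the all-pairs Dijkstra
and the dense eigensolve — in a few seconds on one core.

## Numerical choices

* **Local spectra** come from the SVD of the centered neighbor matrix
  (k×D), zero-padded when D < k; this is more accurate for the small
  singular values than eigendecomposing the Gram matrix.
* **Regularization bias.** `γ = 1e-3·trace(G_i)` is the conventional
  conditioning choice, but it biases the weights away from exact
  barycentric reconstruction by O(γ/λ): on exactly planar data recovery
  saturates at ~1e-3 relative residual (the independent reference
  implementation shows the same floor). The exact-recovery check therefore
  runs with `gamma_scale=1e-10` — the noiseless limit with regularization
  effectively off, where recovery is exact to ~1e-10. The default is kept
  at 1e-3 for noisy data, where the bias is dominated by noise and the
  conditioning is needed.
* **Eigenproblem.** Dense symmetric solver (`scipy.linalg.eigh`, subset of
  the d+1 smallest eigenpairs) up to n=2000, shift-invert Lanczos beyond,
  with a dense retry on failure. The near-zero constant eigenvector is
  discarded. Sign convention: each column's largest-magnitude entry is
  positive, making fits bit-reproducible.
* **Tie-breaks.** All k-NN selections use stable argsort: equal distances
  resolve to the smaller index, deterministically.
* **Disconnected graphs.** Pairs split across components would have
  infinite geodesics (poisoning the mean-distance normalization) — they
  fall back to ambient Euclidean distance, with a logged count. Dropping
  points would silently change the vocabulary; infinities would poison
  every mean.
* **Degenerate neighborhoods.** All-coincident neighbors give a zero Gram
  matrix: weights become uniform (`γ` alone conditions the solve), the
  spectrum split takes its maximum `s_i`, and a zero Householder vector
  yields the identity reflection — no special-casing downstream.
* **Archives.** Model files are uncompressed ZIPs of `.npy` members plus a
  sorted-keys JSON header, with member timestamps pinned to the ZIP epoch:
  identical fits produce byte-identical archives, checkable by checksum.

## Design decisions on open points

* The multi-weight construction follows the published MLLE formulation:
  `α_i = ‖v_i‖/√s_i` and `H_i` the reflection mapping `v_i` to `α_i·1`.
* The `r_i/s_i` split uses the published cumulative-ratio criterion with
  the adaptive median threshold as default; a fixed `eta` is exposed for
  experimentation.
* Frequency ranks default to file row order (released embeddings are
  frequency-sorted); a `word<TAB>count` side file overrides them.
* Multiword terms in evaluation are vectorized as the mean of their
  in-vocabulary tokens; unresolvable terms are skipped by default rather
  than randomized, so correlations never include fabricated scores.
* Window words default to pass-through in `reembed_vocabulary` (exact on
  the window); evaluation experiments re-transform all words, as argued
  above.

## Known limitations

* O(n²) memory and all-pairs shortest paths bound the training window to a
  few thousand words; there is no landmark/approximate-neighbor path.
* The geodesic graph is only as good as its Euclidean k-NN scaffold: if
  `k_graph` neighborhoods span a fold of the manifold, geodesics
  short-circuit and the normalized metric inherits the error (it is
  logged only when the graph disconnects, not when it short-circuits).
* `d = D` re-embedding distributes variance across many near-degenerate
  eigenvectors; cosine similarity in that space emphasizes local structure.
  Pearson correlations benefit more than Spearman on far pairs.
* Out-of-sample extension assumes the new vector lies near the training
  manifold; vectors far off-manifold (e.g. random OOV initializations) are
  mapped through their nearest window neighborhood regardless, with no
  warning.
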