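# Methods

## Model

Every node (cortical surface vertex, pixel, region of interest) carries
a feature vector; pairwise similarity between these vectors defines a
weighted, undirected, non-negative affinity graph `W`. With degrees
`d_i = Σ_j W_ij`, `D = diag(d)` and the Laplacian `L = D − W`, the
one-dimensional embedding minimizing the weighted sum of squared
inter-node distances `U(x) = Σ_ij W_ij (x_i − x_j)²` is an eigenproblem:

* constraint `xᵀx = 1` → standard problem `L x = λ x`;
* constraint `xᵀD x = 1` → generalized problem `L x = λ D x`, which
  prevents high-degree nodes from dominating the embedding. This is the
  package default.

The trivial solution (λ₁ = 0, constant eigenvector) is discarded; the
second eigenpair gives the algebraic connectivity λ₂ and the Fiedler
vector, the principal gradient. Eigenvectors 2…d+1 form a d-dimensional
eigenmap; the first three can be min-max scaled into RGB, and the
Fiedler vector's rank order gives the spectral reordering.

The VB index is `λ₂ / mean(λ₂, …, λ_n)`. Closed forms fix its range:
the uniform complete graph on n nodes has standard spectrum
{0, n, …, n} and generalized spectrum {0, n/(n−1), …}, so VB = 1 in
both; a disconnected graph has λ₂ = 0, so VB = 0. Because
trace(L) = Σ d_i ≥ (n−1) λ₂ (standard) and trace(D⁻¹L) = n (generalized),
the ratio cannot exceed 1 in either problem. The denominator always uses
the eigenvalues of the *same* problem that produced λ₂; mixing problems
would break the [0, 1] bound.

## Affinity construction

The default recipe computes Pearson correlations, clamps negatives to
zero, and maps retained values through `r ↦ 1 − arccos(r)·2/π` (the
angular similarity restricted to [0, 1]). Clamping before the transform
guarantees non-negativity without an arbitrary shift constant;
`arccos(0)·2/π = 1` maps clamped pairs back to weight 0, so sparsity is
preserved. Alternatives (dot product, cosine, signed angular similarity;
constant shift; ε-threshold; union-symmetrized k-NN; binarization) are
selected through `AffinityPolicy`. Scalar angular quantities are
evaluated as `2·atan2(‖u−v‖, ‖u+v‖)` on centered unit vectors rather
than `arccos(corr)`, which keeps full precision at angles near 0° and
180° where arccos loses half the working digits.

Degenerate (zero-variance) feature rows have no defined correlation;
the default policy drops them and returns an index map, with "isolate"
and "error" alternatives. Self-similarity is excluded: the affinity
diagonal is forced to zero before degrees are computed. Self-loops would
cancel in `D − W` but would inflate the normalized problems and the
uniform-graph ceiling used by the VB normalization.

## Analysis modes

* **Full**: one affinity over all nodes; a single VB value plus the
  d-dimensional gradient.
* **Clustered**: affinity restricted to each labelled region; clusters
  with fewer than 3 members yield NaN with a warning.
* **Searchlight**: per vertex, the affinity of the vertex plus its
  one-ring (directly adjacent) neighbours intersected with the mask —
  5–7 nodes on cortical-quality meshes. Neighbourhoods reduced below 3
  usable nodes (mask borders, orphan vertices) yield NaN rather than
  aborting. A k-ring extension exists but is non-canonical.

A graph containing an isolated node is disconnected, so `vb_index`
returns 0 directly in that case instead of failing on the singular
degree matrix; the value is the correct limit even though the
generalized solve is undefined. Direct Laplacian construction keeps the
stricter policy (error by default, optional drop-with-index-map).

## Numerical choices

* Dense symmetric solvers (`scipy.linalg.eigh`) throughout; the
  generalized/random-walk problems are solved via the symmetric form
  `D^{−1/2} L D^{−1/2}` and back-transformed, which keeps the problem
  symmetric-definite. This targets region/searchlight scales (up to a
  few thousand nodes); whole-brain 32k-vertex graphs would need an
  iterative solver and are a documented limitation.
* Eigenvector sign is fixed by making the largest-magnitude component
  positive (ties: lowest index), so gradient maps are reproducible
  rather than defined only up to reflection.
* λ₂-degeneracy (λ₃ − λ₂ below 1e−10 relative) sets a flag on the
  solution: within a degenerate eigenspace the Fiedler vector is only
  defined up to rotation.
* Correlations are clipped to [−1, 1] before arccos (tolerance 1e−12);
  VB values in (−1e−8, 0) from round-off are clamped to 0.
* Spectral-reorder ties are broken by node index via a stable sort.

## Synthetic data

The generator emulates a piecewise-homogeneous cortex: an icosphere
(closed, 5-or-6-neighbour one-rings, `10·4^s + 2` vertices) is split
into contiguous parcels by farthest-point-seeded balanced region
growing, and every vertex receives its parcel's base time series plus
optional i.i.d. Gaussian noise. Defaults — 6 parcels, series length
200, cross-parcel correlation 0.3, noise 0 — describe the study
condition the package's end-to-end checks target; the positive
cross-correlation keeps the whole-surface graph connected under the
zero-negatives policy.

Base series are constructed exactly: an orthonormal zero-mean basis
mixed by the Cholesky factor of a target correlation matrix whose
off-diagonal entries are the nominal cross-correlation plus a small
seeded jitter (≤ ±0.04, shrunk near the feasibility limit so the matrix
stays positive definite). The jitter matters: exactly equal off-diagonal
correlations make the parcel-level quotient graph permutation-symmetric,
its Fiedler eigenvalue degenerate, and the between-parcel gradient
unidentifiable; it also mirrors the spread that sampled series would
show. Pairwise base correlations are therefore within ±0.05 of the
nominal value by construction.

What the synthetic data does *not* model: temporal autocorrelation,
physiological confounds, spatial smoothness of MRI noise, and realistic
parcel geometry. Tests passing on these fixtures demonstrate the
spectral machinery (piecewise-constant gradients, edge detection,
normalization ceilings), not robustness to real MRI noise — on real
data the VB map is affected by smoothing and should be read as a
relative measure.

Pixel demos use HSV features with hue encoded as (cos h, sin h) for
circularity, 8-connected neighbourhoods by default (closest in size to
the mesh one-ring), and the same similarity policy as surfaces.

## Problem sizes

End-to-end surface checks run on subdivision-2 (162-vertex) and
subdivision-3 (642-vertex) icospheres with 6 parcels and length-200
series — the sizes at which the piecewise-constant gradient and
edge-detection contracts are exact and a full run takes seconds. Image
checks use 10–16 pixel rasters against a brute-force per-pixel oracle.

## Known limitations

* Dense eigensolves bound practical whole-region graphs to a few
  thousand nodes.
* No statistical inference on VB or gradient maps (null models for MR
  noise and smoothness are out of scope).
* Surface and lattice grids only; no volumetric searchlight, no CIFTI.
* The constant added under the `shift_constant` policy has no default;
  it is data-dependent and must be chosen by the user.
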