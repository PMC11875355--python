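# Methods

## The model

`nfrfs` performs unsupervised feature selection on a dense sample-by-feature
matrix X ∈ ℝ^{n×d} (rows are samples) by learning a nonnegative *feature
selection matrix* W ∈ ℝ^{d×l} and a *reconstruction coefficient matrix*
H ∈ ℝ^{l×d} so that XWH approximates X, while a sample-similarity matrix
S ∈ ℝ^{n×n} is learned jointly with the factorization.  The optimization
problem is

    min_{W≥0, H≥0, S}  ‖X − XWH‖₂,ₚᵖ
                       + α · Tr(WᵀXᵀLXW)
                       + β · (Tr(1_{d×d}WWᵀ) − Tr(WWᵀ))
                       + γ · ‖S‖²_F

subject to each row of S lying on the probability simplex, where
L = D − (S+Sᵀ)/2 is the graph Laplacian of the symmetrized similarity and
1_{d×d} is the all-ones matrix.  The four terms are:

1. **Robust reconstruction** — ‖M‖₂,ₚᵖ = Σᵢ ‖mᵢ‖₂ᵖ sums the p-th powers of
   the *sample-row* norms of the residual.  For p < 2 large-residual samples
   are down-weighted, giving robustness to outlier samples; p = 2 recovers
   the squared Frobenius loss.
2. **Manifold preservation** — Tr(WᵀXᵀLXW) = ½ Σᵢⱼ ŝᵢⱼ‖Wᵀxᵢ − Wᵀxⱼ‖²
   penalizes projections that separate samples the graph deems similar.
3. **Redundancy control** — Tr(1WWᵀ) − Tr(WWᵀ) = Σ_{i≠j} ⟨wᵢ, wⱼ⟩ penalizes
   overlap between distinct rows of W, discouraging the selection of
   mutually redundant features.
4. **Graph scale** — γ‖S‖²_F regularizes the learned similarity toward
   spreading mass over neighbors; γ is *not* a free hyperparameter but is
   recomputed each iteration from the closed-form S update (below).

An orthogonality penalty of weight λ additionally pushes WᵀW toward the
identity inside the W update; together with nonnegativity it drives W toward
at most one dominant entry per row and column, so that each latent component
maps to (a small group of) concrete features.  After fitting, features are
ranked by the row norms ‖wᵢ‖₂ of W and the top m are selected.

## Optimization

The three blocks are updated alternately.

**U reweighting (IRLS).**  The ℓ2,p row-norm loss is handled by iteratively
reweighted least squares: a diagonal U with
uᵢᵢ = (p/2)(‖rᵢ‖² + ε)^{(p−2)/2}, rᵢ the i-th residual row, turns the
residual term into the weighted quadratic Tr((X−XWH)ᵀU(X−XWH)).  The ε
(default 1e−12) guards the singularity at vanishing residuals for p < 2; at
p = 2 every weight is exactly 1, so the p = 2 path coincides bitwise with a
plain Frobenius implementation.

**W and H multiplicative updates.**  With U, S fixed, W and H follow
nonnegativity-preserving elementwise ratio rules

    W ← W ⊙ [XᵀUXHᵀ + α XᵀŜXW + βW + λW]
          ⁄ [XᵀUXWHHᵀ + α XᵀDXW + βWWᵀW + λ1_{d×d}W]
    H ← H ⊙ [WᵀXᵀUX] ⁄ [WᵀXᵀUXWH]

with Ŝ the symmetrized similarity and D its degree matrix.  Fixed points
satisfy the KKT complementarity condition W ⊙ (den − num) = 0.  All matrix
products are arranged to cost O(ndl + n²l) per update; no d×d or n×n dense
intermediates beyond S itself are formed.

**Closed-form S update.**  With W fixed, each row of S solves a
simplex-constrained quadratic problem in the projected squared distances
dᵢⱼ = ‖Wᵀxᵢ − Wᵀxⱼ‖².  Requiring exactly k positive neighbors fixes the
per-row trade-off γᵢ = (α/2)(k·d_{i,(k+1)} − Σ_{m≤k} d_{i,(m)}) and yields

    sᵢⱼ = (d_{i,(k+1)} − d_{i,(j)}) / (k·d_{i,(k+1)} − Σ_{m≤k} d_{i,(m)})

for the k nearest neighbors of i and 0 elsewhere; γ is the mean of the γᵢ.
The α that formally appears in numerator and denominator of the printed
closed form cancels exactly (it would otherwise break the row-sum-one
constraint); the implementation uses the α-free form, and the unit tests
arbitrate it against an independent sort-based simplex-projection oracle.
Self-similarity is excluded (sᵢᵢ = 0), ties are broken by sample index, and
a degenerate row whose k+1 nearest distances are all equal falls back to
uniform 1/k weights over the k nearest.

**Loop.**  Per iteration: recompute U → update W → update H → (full variant)
recompute projected distances and relearn S and γ → record the objective.
The loop stops at `max_iter` or when the relative objective change falls
below `tol`.  The recorded objective history is non-increasing within
1e−8 relative slack; this is asserted numerically by the tests rather than
proven symbolically.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| α | graph-term weight | 1 | protocol grid {1e−6 … 1e6} |
| β | redundancy-term weight | 1 | protocol grid {1e−6 … 1e6} |
| p | residual norm exponent | 0.5 | grid {0.01, 0.05, 0.1, 0.5, 1}; p=2 = Frobenius |
| k | neighbors per row of S | 5 | desk-scale n; k ≤ n−2 |
| λ | orthogonality penalty | 1e4 | large enough to discourage collinear columns of W |
| l | latent components | 5 | of the order of the expected cluster count |
| max_iter | iteration cap | 300 | ranking stabilizes near convergence; see below |
| tol | relative objective stop | 1e−6 | |
| ε | IRLS / denominator smoothing | 1e−12 | |

The choice of l matters more than the regularization weights on data with
many pure-noise features: with l well above the number of latent cluster
directions, individual high-variance noise features can claim components of
their own and the row-norm ranking degrades as the solver converges.  With
l of the order of the cluster count the components are forced onto the
shared (cluster) structure and the ranking is stable from roughly a
thousand iterations onward.  λ is introduced by the update rules but never
assigned a value in their derivation; 1e4 was fixed once as large enough to
suppress column collinearity without dominating the data terms, and is
configurable.

Initialization draws W and H i.i.d. Uniform(0.1, 1) from the seed — strictly
positive entries, so the multiplicative updates cannot lock spurious zeros.
Identical seeds give bitwise-identical fits.

## Convergence diagnostics

`kkt_residual` reports max |W ⊙ (den − num)|, the largest violation of the
fixed-point complementarity condition.  Each elementwise product carries the
units of the objective (a W entry times a gradient entry), so the default
normalization divides by the current objective value, giving a
dimensionless residual invariant to rescaling the objective; the stricter
`scale="max_product"` variant normalizes by max |W ⊙ den| instead.  Near the
optimum the objective is extremely flat — the printed λ-terms leave the
relative scaling of W against H only weakly determined — so the
complementarity products keep equilibrating long after the relative
objective change falls below 1e−8; the objective-normalized residual is the
appropriate stopping diagnostic at that scale, and the max-product variant
continues to decay (toward ~3e−6 over ~1.5e5 iterations on the benchmark
fixture) when the solver is run past the objective-based stop.

## Synthetic benchmark generator

`make_synthetic` emulates the structure of the clustering benchmarks the
method targets: n rows drawn from c spherical Gaussian clusters (standard
deviation `noise_sd`) whose means differ by `separation` only on the first
`d_informative` columns (cluster j is offset on the informative columns
congruent to j mod c, the split that maximizes per-column between-cluster
variance), padded with `d_noise` i.i.d. Gaussian(0, noise_sd) columns that
carry no class information.  Defaults — n=100, c=3, 10 informative + 190
noise columns, separation-to-noise ratio 5 — are the study conditions used
by the test bench and acceptance script.  For robustness experiments the
rows can be declared 32×32 images and corrupted by `add_block_noise`, which
overwrites uniformly placed rectangles (e.g. 8×8) in every sample.

What the generator deliberately does not emulate: correlated noise,
heteroscedastic features, non-Gaussian cluster shapes, and the strong
inter-feature correlation of real image data (where any pixel is partly
reconstructible from its neighbors).  Passing the synthetic recovery tests
therefore shows that the optimizer finds cluster-bearing features when they
exist and are the only correlated structure; it does not predict accuracy
margins on real benchmarks.

Data are min–max scaled per column to [0, 1] before fitting (constant
columns map to 0).  Nonnegativity of X is required for the multiplicative
updates to preserve the signs of W and H; scaling can be skipped for data
that is already nonnegative.

## Evaluation protocol

Selected feature subsets are scored by clustering X restricted to the
selected columns with K-means (c = number of true classes, 20 restarts with
distinct seeded initializations) and comparing against the true labels by
Hungarian-matched accuracy (optimal assignment on the contingency table)
and normalized mutual information with geometric-mean normalization
(NMI = I(P;Q)/√(H(P)H(Q)); defined as 0 with a warning when either
partition has zero entropy).  Best and mean ± population-std over restarts
are reported.  The sweep harness enumerates the protocol grids
(α, β ∈ {1e−6, 1e−4, 1e−2, 1, 1e2, 1e4, 1e6}, p ∈ {0.01, 0.05, 0.1, 0.5, 1},
m ∈ {20, 40, …, 200}) in long format and reports both the per-feature-count
and overall argmax rows, so either reading of "best" is recoverable.  The
ablation harness compares three variants under shared seeds: `base`
(reconstruction + redundancy only), `base_graph` (adds the manifold term on
the fixed initial graph), and `full` (adaptive S).

## Numerical choices and limitations

- Degenerate constant columns normalize to 0; degenerate equidistant graph
  rows fall back to uniform weights; ε guards every denominator.
- The S row update excludes the diagonal before sorting — otherwise each
  point's nearest neighbor is itself — and symmetrizes S before forming the
  Laplacian, preserving total mass and positive semidefiniteness.
- The update rules are implemented exactly in their multiplicative ratio
  form; entries of W never reach exact zero, they decay geometrically.
  Hard thresholding is never applied.
- No acceleration (momentum, minibatching) and no approximate nearest
  neighbors: the intended regime is desk-scale (n up to a few thousand),
  where the exact O(n²) graph step is affordable.
- Fit cost is O(t·(ndl + n²l)) time and O(n² + nd) space for t iterations.
- The problem is non-convex; different seeds reach different local optima.
  The protocol's repeated-restart evaluation and the grid sweep are the
  intended ways to account for this.
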