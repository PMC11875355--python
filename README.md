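# nfrfs

Unsupervised feature selection by **ℓ2,p-norm feature reconstruction** with
adaptive graph learning (NFRFS), for dense sample-by-feature matrices such
as vectorized images, gene-expression tables, or spectral features, where
class labels are unavailable and most columns are noise or redundancy.

## The model

Given a nonnegative X ∈ ℝ^{n×d} (rows are samples), the method learns a
nonnegative feature selection matrix W ∈ ℝ^{d×l} and reconstruction
coefficients H ∈ ℝ^{l×d} by solving

```
min_{W≥0, H≥0, S}  ‖X − XWH‖₂,ₚᵖ  +  α·Tr(WᵀXᵀLXW)
                   +  β·(Tr(1WWᵀ) − Tr(WWᵀ))  +  γ·‖S‖²_F
```

with each row of the sample-similarity matrix S on the probability simplex
and L the Laplacian of (S+Sᵀ)/2.  The ℓ2,p residual (p ∈ (0,2]) down-weights
outlier samples; the graph term preserves local geometry under an
*adaptively relearned* k-nearest-neighbor graph in the projected space; the
inner-product term Σ_{i≠j}⟨wᵢ,wⱼ⟩ suppresses redundant features; γ is fixed
in closed form by the S update rather than tuned.  Optimization alternates
iteratively-reweighted least squares (for the ℓ2,p term), multiplicative
nonnegative updates of W and H with a soft orthogonality penalty λ, and a
closed-form k-sparse simplex update of each row of S.  Features are ranked
by the row norms ‖wᵢ‖₂ of the fitted W.  See `docs/methods.md` for the
derivations, defaults, and numerical details.

## Worked example

`examples/01_select_features.py` plants 10 informative features among 190
noise features across 3 Gaussian clusters and asks the solver to find them:

```
$ python examples/01_select_features.py
converged=True after 1900 iterations
objective: 174.46 -> 164.47
top-10 features: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
recall of planted informative set: 1.00
```

The planted informative columns are exactly indices 0–9, so a top-10
ranking equal to `[0..9]` is a perfect recovery.  The companion scripts
show the other capabilities: `02_adaptive_graph.py` (structural guarantees
of the learned similarity graph), `03_evaluation_protocol.py` (repeated
K-means scoring — selected features reach ACC 1.000 versus 0.390 for random
features), `04_block_noise.py` (robustness to 8×8 occlusions on 32×32
images), and `05_ablation.py` (base / fixed-graph / adaptive-graph variant
comparison).

The same operations are available from the shell:

```bash
nfrfs synth --n 100 --informative 10 --noise 190 --clusters 3 --seed 0 --out-dir run/
nfrfs fit run/synthetic.csv --p 0.5 --l 5 --max-iter 3000 --out-dir run/
nfrfs rank run/state.npz --m 10 --out-dir run/
```

Every command writes a JSON manifest (resolved configuration, input
fingerprint, outputs) so runs can be reproduced bit-for-bit from the same
seed.

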