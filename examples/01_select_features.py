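"""Select cluster-bearing features from a noisy synthetic benchmark.

Generates 100 samples in 3 Gaussian clusters separated on 10 informative
features, padded with 190 pure-noise features; fits the solver and prints
the top-10 ranked features.  A perfect run ranks exactly the 10 planted
informative columns (indices 0-9) on top.
"""

import numpy as np

from nfrfs import SolverConfig, fit, make_synthetic, minmax_normalize, rank_features

data = minmax_normalize(make_synthetic(n=100, d_informative=10, d_noise=190, c=3, seed=0))
config = SolverConfig(alpha=1.0, beta=1.0, p=0.5, k=5, l=5, max_iter=3000, tol=1e-6, seed=0)
state = fit(data, config)
ranking = rank_features(state, m=10)

print(f"converged={state.converged} after {state.iterations_run} iterations")
print(f"objective: {state.objective_history[0]:.2f} -> {state.objective_history[-1]:.2f}")
print(f"top-10 features: {sorted(int(i) for i in ranking.selected)}")
recall = len(set(range(10)) & set(int(i) for i in ranking.selected)) / 10
print(f"recall of planted informative set: {recall:.2f}")
print("(1.00 means every planted feature was recovered in the top 10)")
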