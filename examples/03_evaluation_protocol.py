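"""Score a feature selection with the repeated K-means protocol.

Fits the solver on the synthetic benchmark, then clusters (a) the top-10
selected features and (b) 10 random features with 20 seeded K-means
restarts each, reporting Hungarian-matched accuracy (ACC) and normalized
mutual information (NMI).  Selected features should far outperform random
ones when the planted structure was found.
"""

import numpy as np

from nfrfs import SolverConfig, fit, make_synthetic, minmax_normalize, rank_features
from nfrfs.metrics import evaluate_selection

data = minmax_normalize(make_synthetic(seed=0))
state = fit(data, SolverConfig(max_iter=3000, tol=1e-6, seed=0))
ranking = rank_features(state, m=10)

score_sel = evaluate_selection(data, ranking.selected, n_repeats=20, seed=0)
random_feats = np.random.default_rng(1000).choice(data.d, 10, replace=False)
score_rnd = evaluate_selection(data, random_feats, n_repeats=20, seed=0)

print(f"selected features: ACC best/mean {score_sel.acc_best:.3f}/{score_sel.acc_mean:.3f}, "
      f"NMI best/mean {score_sel.nmi_best:.3f}/{score_sel.nmi_mean:.3f}")
print(f"random features:   ACC best/mean {score_rnd.acc_best:.3f}/{score_rnd.acc_mean:.3f}, "
      f"NMI best/mean {score_rnd.nmi_best:.3f}/{score_rnd.nmi_mean:.3f}")
print("(ACC=1.0 on the selected subset means K-means recovers the planted "
      "clusters perfectly once noise features are removed)")
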