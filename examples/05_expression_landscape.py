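"""Cluster the single-cell expression landscape and call positivity.

The workflow z-scores each marker, projects onto the principal axes that
capture 95 % of the variance, and K-means-clusters the reduced features.
On a phantom with six mutually exclusive marker-high clusters plus a
diffuse low-expression mass, the planted structure is recovered almost
perfectly (adjusted Rand index ~0.97).
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import mplexquant as mq
from mplexquant.synthetic import default_cluster_profiles

x, true_labels = mq.sample_cluster_expression(
    default_cluster_profiles(), n_cells=5000, seed=0
)
model, labels, profile, occurrence = mq.cluster_cells(
    x, var_frac=0.95, k=9, seed=0
)
print(f"principal axes retained: {model.n_components} "
      f"(cumulative variance {model.explained_variance_ratio.sum():.3f})")
print(f"ARI vs planted clusters: "
      f"{adjusted_rand_score(true_labels, labels):.3f}")
print("cluster occurrence fractions (sum to 1):")
print(occurrence.round(3).to_string())
print("per-cluster mean z-scored profile (heatmap data), first rows:")
print(profile.head(4).round(2).to_string())

# positivity and co-occurrence: fraction of X+ cells that are Y+
calls = mq.call_positivity(x, {m: "otsu" for m in model.markers})
res = mq.cooccurrence_stats(calls, "P21", "P53")
print(f"P(P53+ | P21+) = {res.fraction:.3f} "
      f"[95% CI {res.ci_low:.3f}, {res.ci_high:.3f}], "
      f"n(P21+) = {res.n_x_positive}")
print("(exclusive clusters: markers rarely co-occur, so the fraction is small)")

emb = mq.embed_2d(model.reduce(x[model.markers].to_numpy()), seed=0)
print(f"2D embedding computed for {len(emb)} cells (for plotting)")
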