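"""Decompose the six group networks into shared low-rank prototypes.

COVSCA approximates each masked network matrix as a nonnegative combination
of two rank-2 prototype matrices: the coefficients place every network in a
2-D score space (networks with similar correlation structure sit together),
and the prototype loadings say which fractions drive the differences.
On matrices generated exactly from the model the fit is perfect (100%).
"""

import liponet as lp
from liponet.covsca import loading_table

# exact model-generated input: the fitter recovers it perfectly
mats, coeff, protos = lp.generate_covsca_instances(6, 2, [2, 2], 21, seed=1)
exact = lp.fit_covsca(mats, L=2, ranks=[2, 2], n_starts=10, seed=2)
print(f"goodness of fit on exact low-rank input: {exact.gof:.2f}%")

# the six study networks
table = lp.generate_cohort(seed=7)
groups = lp.stratify_by_age(table)
nets = lp.infer_group_networks(table, groups, lp.PclrcParams(niter=200), seed=5)
model = lp.fit_covsca([n.weights for n in nets.values()], L=2, ranks=[2, 2],
                      n_starts=10, seed=6, matrix_labels=list(nets))
print(f"\ngoodness of fit on the six group networks: {model.gof:.1f}%")
print("\nscores (one row per network; the 2-D coordinates of Figure-style "
      "score plots):")
print(lp.covsca_scores(model).round(3))

pruned = lp.prune_loadings(model, z_min=1,
                           node_names=list(nets["M"].nodes))
kept = (pruned != 0).sum()
print(f"\nloadings retained after |z| >= 1 pruning, per column:\n{kept}")
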