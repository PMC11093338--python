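"""Score the pairwise model on statistics it was not fitted to.

Beyond KL-based goodness, the model is judged on third-order correlations
C_ijk, their connected versions, and H_m (the probability that m neurons are
simultaneously active). G_C, G_C~ and G_H compare the pairwise model's
prediction error against the independent model's. Data come from a pairwise
ground truth, so the pairwise model should win on raw triples and counts;
connected third-order correlations are near zero and hard for either model.
"""

import numpy as np

import spikemaxent as sm
from spikemaxent.benchmarks import random_sparse_model

truth = random_sparse_model(8, np.random.default_rng(5), j_max=0.25)
T = 100_000
raster = sm.sample_model(truth, T, seed=6)
moments = sm.compute_moments(raster)

pair = sm.fit_pseudolikelihood(raster)
ind = sm.fit_independent(moments)

data = (sm.triple_stats(raster), sm.count_distribution(raster))
pair_pred = sm.model_predicted_stats(pair, T, seed=7, triples=data[0].triples)
ind_pred = sm.model_predicted_stats(ind, T, seed=8, triples=data[0].triples)
rep = sm.prediction_goodness(data, pair_pred, ind_pred)

print(f"third-order correlations : G_C  = {rep.g_c:+.3f}")
print(f"connected third order    : G_C~ = {rep.g_c_tilde:+.3f}")
print(f"simultaneous-count law   : G_H  = {rep.g_h:+.3f}")
print("(1 = pairwise model perfect, 0 = no better than independent;"
      " negative values are flagged, never dropped)")
if rep.flags:
    print("flags:", rep.flags)
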