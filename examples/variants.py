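"""Qualitative signatures of the model variants.

Shows what each structural ingredient contributes: removing regeneration
splits the population into a silent pool and a narrow cluster of very strong
synapses; replacing the Gaussian daily increments with exponential ones of
unequal rates makes weights collapse or blow up; the cluster-stability
protocol shows the strong-synapse count N_st hovering in a narrow band for
years in the standard model.
"""

import numpy as np

from spinedyn import ModelParams, cluster_stability_protocol, init_ensemble, run

# --- no regeneration: bimodal, large silent pool -------------------------
p = ModelParams(variant="no_regeneration")
ens = init_ensemble(300, p, seed=5)
run(ens, 4_000, p, record_every=None)
silent = 1.0 - ens.active.mean()
print("no-regeneration variant after 4,000 days:")
print(f"  silent fraction {silent:.2f}; median active W "
      f"{np.median(ens.weights[ens.active]):.1f} (bimodal: basal pool vs very strong)")

# --- exponential increments with unequal decay rates ---------------------
for lam1, lam2, label in [(0.5, 3.0, "LTP-dominated"), (3.0, 0.5, "LTD-dominated")]:
    pe = ModelParams(variant="exponential_increments", lambda1=lam1, lambda2=lam2)
    ee = init_ensemble(100, pe, seed=5)
    run(ee, 500, pe, record_every=None)
    print(f"exponential increments, rates ({lam1}, {lam2}) [{label}]: "
          f"median W {np.median(ee.weights):.3g}, silent {1 - ee.active.mean():.2f}")

# --- cluster stability in the standard model -----------------------------
res = cluster_stability_protocol(ModelParams(), seed=5, horizon=1_000,
                                 n_clusters=300, burn_in_days=4_000)
print("standard model, strong-synapse count N_st over 1,000 days:")
print(f"  mean N_st {res.summaries['mean_n_strong']:.2f}; fraction of cluster-days "
      f"with N_st in [4, 7]: {res.summaries['fraction_cluster_days_4_7']:.3f}")
print()
print("Regeneration and Gaussian, weight-proportional increments are both")
print("needed for a stable unimodal distribution; with them, each cluster")
print("maintains a narrow band of strong synapses indefinitely.")
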