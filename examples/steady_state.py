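"""Steady-state weight distribution of the standard clustered model.

Runs a reduced ensemble (200 clusters of 10 synapses) past burn-in and
prints the headline steady-state statistics: the log-normal shape of the
weight distribution, the fraction of synapses silenced, and the size of the
daily weight fluctuations.  At the full scale (1,000 clusters, longer
burn-in) the same summaries are produced by
``spinedyn steady-state --seed 1 --out out/``.
"""

from spinedyn import ModelParams, steady_state_protocol

result = steady_state_protocol(ModelParams(), seed=1, n_clusters=200,
                               burn_in_days=4_000)
s = result.summaries

print("steady state of the standard clustered model (200 clusters x 10 synapses)")
print(f"  active synapses:        {s['n_active']:.0f} / {s['n_synapses']:.0f} "
      f"(silent fraction {s['silent_fraction']:.3f})")
print(f"  mean weight (all):      {s['mean_w_all']:.3f}")
print(f"  ln-weight fit:          mu = {s['lognormal_mu']:.3f}, "
      f"sigma = {s['lognormal_sigma']:.3f}  (log-normal MLE, active synapses)")
print(f"  active weight range:    {s['active_log_range']:.1f} natural-log units")
print(f"  daily change:           mean |dW|/W = {s['percent_daily_change']:.1f}% ; "
      f"normal-fit sd of dW = {s['delta_sd_histfit']:.3f}")
print(f"  strong synapses:        mean N_st per cluster = {s['mean_n_strong']:.2f}")
print()
print("The unimodal, heavy-tailed weight distribution (sigma of ln W near 1)")
print("emerges from multiplicative LTP/LTD noise plus cluster-level resource")
print("competition; small synapses fluctuate relatively more, and a few percent")
print("of synapses sit silent at the basal weight awaiting regeneration.")
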