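"""Persistence of an imposed engram-like pattern of strong synapses.

After the ensemble reaches steady state, the first five synapses of every
cluster are reset to a high weight (5.0) and the rest to a low weight (0.5),
emulating strong potentiation of a memory trace.  The script follows the
potentiated subset for 700 days and prints how far its mean weight stays
above the steady-state average.
"""

from spinedyn import ModelParams, memory_imprint_protocol

result = memory_imprint_protocol(ModelParams(), seed=3, t_reset=100,
                                 follow_days=700, sample_every=50,
                                 n_clusters=200, burn_in_days=4_000)
s = result.summaries
trace = result.tables["imprint_trace"]

print("memory imprint: synapses 1-5 of every cluster reset to W = 5.0")
print(f"  steady-state mean W:          {s['steady_state_mean_w']:.3f}")
print(f"  imprinted mean at reset:      {s['imprinted_mean_initial']:.3f}")
print(f"  imprinted mean after 700 d:   {s['imprinted_mean_final']:.3f} "
      f"({s['imprinted_over_steady_ratio']:.2f}x the steady-state mean)")
print(f"  imprinted mean - 1 sd:        {s['imprinted_minus_sd_final']:.3f}")
print()
print("decay of the imprinted subset (every 100 days):")
for _, row in trace.iloc[::2].iterrows():
    print(f"  day {row['day']:4.0f}: mean {row['imprinted_mean']:.2f} "
          f"(sd {row['imprinted_sd']:.2f}), non-imprinted {row['other_mean']:.2f}")
print()
print("The potentiated subset decays slowly toward the steady state but its")
print("mean remains well above it after 700 days: the imposed pattern of")
print("strong synapses — a candidate engram — outlives molecular turnover by")
print("years without any bistable switch.")
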