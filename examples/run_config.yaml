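# Example run configuration for the spinedyn CLI.
#
#   spinedyn steady-state --config examples/run_config.yaml --out out/
#
# Model parameters default to the standard values; any of them can be set
# here (unknown keys are rejected). The seed is mandatory.
seed: 1
n_clusters: 200
burn_in_days: 4000

# model parameter overrides
N_cl: 10
variant: standard
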