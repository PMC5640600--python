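# Demo study: one shared causal variant in a 600 kb region.
# Run:  decstat run --config examples/demo_config.yaml --out demo_run/
n_individuals: 500
n_snps: 60
causal_index_expr: 30
h2_expr: 0.25
causal_index_dis: 30
log_or_dis: 0.6
seed: 1
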