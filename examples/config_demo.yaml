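# Demo configuration for `designscreen run -c examples/config_demo.yaml`.
# Omitted keys take the defaults documented in designscreen.pipeline.RunConfig.
seed: 1
out_dir: scratch/demo_run
n_per_strategy: 1000
k_per_strategy: 150
depth: 30000
n_surrogate_models: 15
n_trees: 40
nnk_n_sequences: 5000
nnk_replicates: 3
n_struct_models: 25
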