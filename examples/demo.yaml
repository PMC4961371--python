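# Demo analysis: a scaled synthetic ensemble (5 replicates x 400 ns over a
# 120-lipid PC/PS/PIP2 bilayer) through the full pipeline.
# Run:  phmem run-all --config examples/demo.yaml
seed: 7
output_dir: demo_out
generate:
  total_lipids: 120
  composition: {PC: 0.75, PS: 0.20, PIP2: 0.05}
  n_replicates: 5
  n_frames: 400
  mean_binding_time_ns: 100.0
landscape:
  convergence_blocks: 2
plots:
  enabled: true
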