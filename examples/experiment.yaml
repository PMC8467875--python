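# Default experiment: dual-source scanner at the standard dose, all five
# virtual monoenergetic energies, elastic-net classification.
seed: 0
energies: [40, 50, 75, 120, 190]
doses: [15]
scanners: [DSDE]
preprocess:
  target_spacing_mm: [1.0, 1.0, 1.0]
  interp_order: 5
  rescale_scale: 500.0
  bin_width: 25.0
  apply_rescale: true
ccc_threshold: 0.9
dr_threshold: 0.9
families: [elastic_net_logistic]
write_volumes: false
out_dir: results
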