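# One-command synthetic demo: generate a small cohort with known ground
# truth, classify XCI status, and run the association + outcome statistics.
#   xci-scope run --config examples/demo_config.yaml
seed: 1
outdir: demo_output
simulate: true
simulation:
  n_samples:
    endometrioid: {preserved_Xi: 20, Xa_plus: 20, two_Xa: 20}
    serous: {preserved_Xi: 20, Xa_plus: 20, two_Xa: 20}
  n_x_island_probes: 120
  n_x_nonisland_probes: 12
  n_autosomal_island_probes: 300
inference:
  k: 3
  t_hyper: 0.35
  t_hypo: 0.18
  t_xist: 6.5
  arm_cnv_cutoff: 0.3
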