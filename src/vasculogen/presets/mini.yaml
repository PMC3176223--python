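# Smallest useful scale for sweep experiments: 100x100 lattice with the
# reference density preserved (1100 cells on 400x400 -> 69 cells).
params:
  D: 10.0
  alpha_V: 0.003
  alpha_E: 0.003
  k_bind: 0.5
  gamma_s: 0.001
  T_fluct: 40.0
  A_target: 100.0
  lambda_area: 50.0
  J_cc: 40.0
  J_cm: 30.0
  mu_total: 350.0
  bound_fraction: 0.8
  neighbor_order: 2
  lattice_side: 100
  pixel_size: 2.0
  mcs_seconds: 1.0
  pde_substeps: 12
  seed: 0
scenario:
  n_cells: 69
  init_mode: regular
  total_mcs: 1500
  field_mode: normal
  snapshot_stride: 100
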