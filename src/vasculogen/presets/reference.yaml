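# Reference set-up: 400x400 lattice at 2 µm/pixel (0.64 mm² tissue),
# 1100 cells (~1720 cells/mm², the density measured in early quail
# vascular plexus), 1 s per MCS, run for 3000 MCS (~1 h of development).
# Concentrations in arbitrary units; see docs/methods.md for rate choices.
params:
  D: 10.0          # µm²/s, soluble VEGF
  alpha_V: 0.003   # a.u./s, uniform paracrine VEGF supply
  alpha_E: 0.003   # a.u./s, ECM binding-site production under cells
  k_bind: 0.5      # 1/(a.u. s)
  gamma_s: 0.001   # 1/s, soluble VEGF degradation
  T_fluct: 40.0
  A_target: 100.0  # px (400 µm² per cell)
  lambda_area: 50.0
  J_cc: 40.0
  J_cm: 30.0       # > J_cc/2: positive cell-medium surface tension
  mu_total: 350.0
  bound_fraction: 0.8
  neighbor_order: 2
  lattice_side: 400
  pixel_size: 2.0  # µm
  mcs_seconds: 1.0
  pde_substeps: 12
  seed: 0
scenario:
  n_cells: 1100
  init_mode: regular
  total_mcs: 3000
  field_mode: normal
  snapshot_stride: 100
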