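# Example run configuration for `ventplume run-all --config configs/example.yaml`
# Paths are relative to the invocation directory.
site_table_path: results/sites.csv
output_dir: results/run_example
seed: 0
log_level: INFO

model:
  V_harv: 1000.0          # harvest volume, m3 per mol biomass
  alpha: 1.16e-8          # mortality rate, 1/s
  duration: 2592000.0     # 30 days, s (300-day runs: 25920000.0)
  initial_cells: 1.0e5    # cells per ml
  cell_carbon: 2.0e-14    # gC per cell

hydro:
  alpha_j: 0.08
  alpha_p: 0.16
  Fr_p: 1.6
  n_cells: 300
  fallback_dilution: 1.0e5

budget:
  plume_height: 200.0     # m
  area_small: 1000.0      # km2
  area_large: 400000.0    # km2
  large_fraction_mixed: 0.10
  Q_sw: 0.001             # MW
  Q_vents: 1.0e6          # MW
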