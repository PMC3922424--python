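# Demo study: 30 control + 30 autism-group subjects over two sites on a
# compact synthetic grid, with a pronounced left-lateralization deficit
# (Fisher z -0.5) planted on the Wernicke--posterior-cingulate connection
# of the autism group.  Desk-scale cohorts use a per-site minimum of 10
# subjects instead of the full-scale default of 20.
criteria: A
q: 0.05
min_site_n: 10
cohort:
  n_control: 30
  n_autism: 30
  n_sites: 2
  grid_dims: [12, 12, 8]
  voxel_mm: 3.0
  tr_seconds: 2.0
  n_volumes: 120
  base_edge_z: 0.3
  noise_sd: 0.3
  seed: 7
  lateralization_effects:
    - {hub_a: We, hub_b: PC, dz_control: 0.0, dz_autism: -0.5}
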