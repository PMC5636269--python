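lattice:
  n_voxels_per_edge: 100
  voxel_size_um: 10.0
  duration_days: 50.0
  dt_hours: 0.25
rules:
  p_kill_neg: 0.15
  p_kill_pos: 0.1
  p_pdl1_induction: 0.2
  p_supp: 0.08
  induction_on_contact: false
  il2_division_threshold: 0.012
  cancer_cycle_time_h: 36.0
  t_cell_cycle_time_h: 8.0
  max_t_cell_divisions: 8
  division_retry_h: 1.0
  t_cell_speed_um_min: 1.0
  cancer_speed_um_min: 0.02
  t_cell_lifespan_h: 168.0
  dead_clearance_time_h: 24.0
  spontaneous_death_rate_h: 0.001
  k_a: 20.0
  k_i: 0.1
  r_base: 0.08
  lambda_vasc_per_um: 0.01
  base_entry_density: 0.02
cytokine:
  diffusion_um2_s: 10.0
  decay_rate_h: 0.693
  secretion_rate_h: 1.0
  substeps_per_dt: 10
treatment:
  enabled: false
  start_day: 30.0
  m_supp: 0.8
schema_version: 1
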