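schema_version: 1
master_seed: 0
beam:
  sigma_mm: 3.0
  spot_separation_mm: 5.0
  spill_charge_nc: 4.96
  uhdr_dose_rate_gy_s: 726.3
  cdr_dose_rate_gy_s: 1.0
pulse:
  pulse_width_uhdr_ms: 50.0
  micropulse_width_ns: 24.0
  micropulse_period_ns: 143.0
  interpulse_delay_s: 2.0
  cdr_pulse_width_max_s: 8.0
roi:
  face_side_um: 50.0
  depth_um: 20.0
track:
  w_ev: 62.5
  spur_sigma_nm: 0.3
  electron_spread_scale: 0.2
  electron_thermalization_factor: 2.5
  cross_section_scale: 1.0
  species_yield_targets:
    e_h: 4.9
    OH: 5.5
    H: 0.62
    H3O: 4.9
    OHm: 0.5
    H2: 0.15
    H2O2: 0.0
diffusion:
  e_h: 4900000000.0
  OH: 2800000000.0
  H3O: 9500000000.0
  H: 7000000000.0
  OHm: 5300000000.0
  H2O2: 2300000000.0
  H2: 4800000000.0
chemistry: null
stepper:
  ladder_ps:
  - 0.1
  - 1.0
  - 3.0
  - 10.0
  - 100.0
  - 1000.0
  dt_min_ps: 0.1
  dt_max_ps: 1000.0
  record_every_ps: 2.0
  neighbor_mode: tree
experiment:
  repeats: 100
  repeats_low_energy: 20
  t_chem_us: 1.0
  record_log_points: 400
  round_protons: true
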