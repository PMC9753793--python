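arms:
  FD1:
    e_eq_effect: null
    h_effect: 0.708
    ihc_chac_effect: 0.75
    ihc_chb_effect: 1.0
    k_effect: 1.801
    n_animals_refraction: 22
    n_animals_uct: 6
    re_iod_mean: -2.35
    re_iod_sd: 1.11
  FD3:
    e_eq_effect: null
    h_effect: 0.601
    ihc_chac_effect: 0.75
    ihc_chb_effect: 0.7
    k_effect: 2.314
    n_animals_refraction: 22
    n_animals_uct: 6
    re_iod_mean: -4.07
    re_iod_sd: 0.72
  naive:
    e_eq_effect: null
    h_effect: 1.0
    ihc_chac_effect: 1.0
    ihc_chb_effect: 1.0
    k_effect: 1.0
    n_animals_refraction: 22
    n_animals_uct: 6
    re_iod_mean: 0.02
    re_iod_sd: 0.37
assay:
  digest_volume_mL: 0.2
  dmmb_intercept: 0.05
  dmmb_slope: 0.02
  dmmb_standards:
  - 0.0
  - 5.0
  - 10.0
  - 20.0
  - 40.0
  dna_total_ug: 1.5
  dry_mass_mg: 0.15
  ihc_background: 300.0
  ihc_band:
  - 24
  - 40
  ihc_buffer_intensity: 500.0
  ihc_chac_ratio: 1.7
  ihc_chb_ratio: 1.6
  ihc_shape:
  - 64
  - 160
  pico_intercept: 0.02
  pico_slope: 0.05
  pico_standards:
  - 0.0
  - 2.0
  - 5.0
  - 10.0
  - 20.0
  plate_noise_au: 0.005
  sgag_mass_fraction_ug_mg: 10.0
  sgag_sd_log_animal: 0.15
  sgag_sd_log_eye: 0.08
baseline_re_iod_mean: -0.13
baseline_re_iod_sd: 0.67
biometry:
  means:
  - 105.0
  - 320.0
  - 2000.0
  - 650.0
  - 230.0
  opacity_rate: 0.0
  re_contra_mean: -0.1
  re_contra_sd: 0.5
  refractive_index: 1.39
  sd_animal:
  - 3.0
  - 10.0
  - 30.0
  - 25.0
  - 8.0
  sd_eye:
  - 2.0
  - 5.0
  - 10.0
  - 12.0
  - 4.0
material:
  e_eq_mean: 50000.0
  h_plus_mean: 1000000.0
  k_mean: 3.0e-16
  sd_log_animal_e: 0.25
  sd_log_animal_h: 0.25
  sd_log_animal_k: 0.35
  sd_log_eye_e: 0.08
  sd_log_eye_h: 0.08
  sd_log_eye_k: 0.12
protocol:
  diameter_m: 0.001
  hold_duration: 3000.0
  load_noise_uN: 10.0
  n_hold_samples: 110
  n_ramp_samples: 12
  n_steps: 3
  oracle_dt: 0.75
  oracle_n_radial: 64
  ramp_duration: 10.0
  samples_per_eye: 1
  strain_jitter_halfwidth: 0.015
  strain_sens_log_h: -3.0
  strain_sens_log_k: -8.0
  target_strain: 0.05
  thickness_um: 50.0
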