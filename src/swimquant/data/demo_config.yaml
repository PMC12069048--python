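# Demo experiment: 12 saline-control vs 12 treated fish, 5 min at 15 fps.
# The treated group emulates a surface-biased, high-activity phenotype:
# strong upper-half preference and a frequently visited rapid regime.
fps: 15.0
geometry:
  surface_y: 20.0
  bottom_y: 420.0
  width_px: 600.0
  px_per_cm: null
qc:
  likelihood_threshold: 0.9
  max_gap_frames: null
kinematics:
  window_s: 1.0
  k_sem: 3.0
spatial:
  heatmap_nx: 50
  heatmap_ny: 50
stats:
  alpha: 0.05
groups:
  control: control
  treated: treated
simulate:
  n_per_group: 12
  duration_s: 300.0
  shared:
    regime_speeds: [40.0, 140.0]
    heading_persistence: 0.95
    jitter_sd_px: 1.0
    p_drop: 0.02
    depth_sd_px: 20.0
    vertical_step_px: 0.8
    speed_cv: 0.1
  control:
    p_upper: 0.2
    regime_switch_prob: [0.01, 0.20]
  treated:
    p_upper: 0.8
    regime_switch_prob: [0.05, 0.15]
qpcr:
  slope: -3.3219280948873623
  intercept: 40.0
  dilution_points: 6
  dilution_factor: 10.0
  ct_noise_sd: 0.15
  n_fish_per_group: 12
  effect_multiplier: [1.6, 2.4, 1.8, 1.2]
  fish_scale_sd: 0.2
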